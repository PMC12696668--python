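"""Ultrasound pulse-train and intensity arithmetic.

All exchange units are fixed once: intensities in W/cm**2, pressures in Pa
(MPa only inside the mechanical index), distances in mm, times in seconds.
The free-water to in-situ conversions implemented here are the two
conventions used in low-intensity TUS work: a fixed fractional skull
attenuation applied to the free-water spatial-peak pulse-average intensity
(Isppa), and the plane-wave relation I = p**2 / (2 rho c) linking the
simulated pressure amplitude to intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SonicationProtocol",
    "CouplingStack",
    "AcousticConstants",
    "DoseEstimates",
    "derive_protocol",
    "tpo_depth",
    "isppa_from_pressure",
    "pressure_from_isppa",
    "fixed_attenuation_estimate",
    "transmission_rate",
    "mechanical_index",
    "estimate_doses",
]

#: W/m**2 per W/cm**2
_CM2_PER_M2 = 1.0e4


@dataclass(frozen=True)
class AcousticConstants:
    """Homogeneous-medium constants for the plane-wave approximation."""

    rho: float = 1000.0  # density, kg/m**3
    c: float = 1500.0  # sound speed, m/s

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.c <= 0:
            raise ValueError("density and sound speed must be positive")


@dataclass(frozen=True)
class SonicationProtocol:
    """A rectangular pulse train: PD-long pulses every PRI for PTD seconds.

    Defaults are the 5 Hz repetitive TUS protocol: an 80 s train of 20 ms
    pulses repeated every 200 ms (PRF 5 Hz, 10% duty cycle, 400 pulses) at a
    free-water Isppa of 10 W/cm**2 and 500 kHz fundamental frequency.
    """

    f0: float = 500e3  # fundamental frequency, Hz
    pd: float = 0.020  # pulse duration, s
    pri: float = 0.200  # pulse repetition interval, s
    ptd: float = 80.0  # pulse train duration, s
    isppa_fw: float = 10.0  # free-water Isppa, W/cm**2

    def __post_init__(self) -> None:
        if not (0 < self.pd <= self.pri <= self.ptd):
            raise ValueError("require 0 < PD <= PRI <= PTD")
        if self.f0 <= 0:
            raise ValueError("fundamental frequency must be positive")
        if self.isppa_fw < 0:
            raise ValueError("free-water Isppa must be non-negative")

    @property
    def prf(self) -> float:
        """Pulse repetition frequency, Hz."""
        return 1.0 / self.pri

    @property
    def duty_cycle(self) -> float:
        """On-fraction of the train, in (0, 1]."""
        return self.pd / self.pri

    @property
    def n_pulses(self) -> int:
        return int(round(self.ptd / self.pri))


@dataclass(frozen=True)
class CouplingStack:
    """Coupling-path bookkeeping between the transducer face and the target.

    The depth dialled into the transducer power output unit (TPO) must
    include the standoff added by the coupling gel film and gel pad.
    """

    target_depth: float = 33.0  # scalp-to-target, mm
    gel_pad: float = 10.0  # mm
    gel_film: float = 0.5  # mm

    @property
    def tpo_depth(self) -> float:
        return tpo_depth(self.target_depth, self.gel_pad, self.gel_film)


def derive_protocol(pd: float, pri: float, ptd: float) -> tuple[float, float, int]:
    """Return (PRF in Hz, duty cycle as a fraction, pulse count).

    round() guards float representation of exact ratios such as 80/0.2.
    """
    proto = SonicationProtocol(pd=pd, pri=pri, ptd=ptd)
    return proto.prf, proto.duty_cycle, proto.n_pulses


def tpo_depth(target_depth: float, gel_pad: float, gel_film: float) -> float:
    """Depth setting for the TPO: target depth plus coupling standoffs, mm."""
    for name, v in (("target_depth", target_depth), ("gel_pad", gel_pad),
                    ("gel_film", gel_film)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return target_depth + gel_pad + gel_film


def isppa_from_pressure(p, constants: AcousticConstants = AcousticConstants()):
    """Plane-wave intensity I = p**2 / (2 rho c), W/cm**2, from pressure in Pa.

    Accepts scalars or arrays; negative pressure amplitudes are rejected for
    scalars (arrays of signed pressure are squared, so the magnitude is used).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 0 and p < 0:
        raise ValueError("pressure amplitude must be non-negative")
    out = (p ** 2) / (2.0 * constants.rho * constants.c) / _CM2_PER_M2
    return float(out) if out.ndim == 0 else out


def pressure_from_isppa(isppa, constants: AcousticConstants = AcousticConstants()):
    """Inverse plane-wave relation: p = sqrt(2 rho c I), Pa, from W/cm**2."""
    isppa = np.asarray(isppa, dtype=float)
    if np.any(isppa < 0):
        raise ValueError("intensity must be non-negative")
    out = np.sqrt(2.0 * constants.rho * constants.c * isppa * _CM2_PER_M2)
    return float(out) if out.ndim == 0 else out


def fixed_attenuation_estimate(isppa_fw: float, attenuation: float = 0.75) -> float:
    """In-situ Isppa under a fixed fractional skull attenuation.

    attenuation = 0.75 means 75% of the free-water intensity is lost.
    """
    if not (0.0 <= attenuation < 1.0):
        raise ValueError("attenuation must lie in [0, 1)")
    return isppa_fw * (1.0 - attenuation)


def transmission_rate(isppa_tc: float, isppa_fw: float) -> float:
    """Percentage of free-water intensity transmitted into the brain."""
    if isppa_fw <= 0:
        raise ValueError("free-water Isppa must be positive")
    return 100.0 * isppa_tc / isppa_fw


def mechanical_index(peak_neg_pressure_mpa: float, f0_mhz: float) -> float:
    """MI = peak negative pressure [MPa] / sqrt(frequency [MHz])."""
    if f0_mhz <= 0:
        raise ValueError("frequency must be positive")
    if peak_neg_pressure_mpa < 0:
        raise ValueError("peak negative pressure must be non-negative")
    return peak_neg_pressure_mpa / np.sqrt(f0_mhz)


@dataclass(frozen=True)
class DoseEstimates:
    """All intensity/MI quantities derivable from a protocol.

    ``isppa_tc_simulated`` is the simulation-based (or synthetic-field) in-situ
    estimate; when absent, transmission and MI fall back to the fixed
    attenuation estimate.
    """

    protocol: SonicationProtocol
    coupling: CouplingStack = field(default_factory=CouplingStack)
    constants: AcousticConstants = field(default_factory=AcousticConstants)
    attenuation: float = 0.75
    isppa_tc_simulated: float | None = None

    @property
    def isppa_tc_fixed(self) -> float:
        return fixed_attenuation_estimate(self.protocol.isppa_fw, self.attenuation)

    @property
    def isppa_tc(self) -> float:
        if self.isppa_tc_simulated is not None:
            return self.isppa_tc_simulated
        return self.isppa_tc_fixed

    @property
    def transmission_pct(self) -> float:
        return transmission_rate(self.isppa_tc, self.protocol.isppa_fw)

    @property
    def peak_neg_pressure_mpa(self) -> float:
        """Plane-wave inversion of the in-situ Isppa, MPa."""
        return pressure_from_isppa(self.isppa_tc, self.constants) / 1e6

    @property
    def mechanical_index(self) -> float:
        return mechanical_index(self.peak_neg_pressure_mpa, self.protocol.f0 / 1e6)

    def as_dict(self) -> dict:
        """Flat report, Table-1-style plus derived pulse-train quantities."""
        proto = self.protocol
        return {
            "f0_hz": proto.f0,
            "pulse_duration_s": proto.pd,
            "pulse_repetition_interval_s": proto.pri,
            "pulse_train_duration_s": proto.ptd,
            "prf_hz": proto.prf,
            "duty_cycle_pct": 100.0 * proto.duty_cycle,
            "n_pulses": proto.n_pulses,
            "tpo_depth_mm": self.coupling.tpo_depth,
            "target_depth_mm": self.coupling.target_depth,
            "isppa_fw_w_cm2": proto.isppa_fw,
            "attenuation_fraction": self.attenuation,
            "isppa_tc_fixed_w_cm2": self.isppa_tc_fixed,
            "isppa_tc_simulated_w_cm2": self.isppa_tc_simulated,
            "transmission_pct": self.transmission_pct,
            "peak_neg_pressure_mpa": self.peak_neg_pressure_mpa,
            "mechanical_index": self.mechanical_index,
        }


def estimate_doses(
    protocol: SonicationProtocol | None = None,
    coupling: CouplingStack | None = None,
    constants: AcousticConstants | None = None,
    attenuation: float = 0.75,
    isppa_tc_simulated: float | None = None,
) -> DoseEstimates:
    """Convenience constructor with study defaults."""
    return DoseEstimates(
        protocol=protocol or SonicationProtocol(),
        coupling=coupling or CouplingStack(),
        constants=constants or AcousticConstants(),
        attenuation=attenuation,
        isppa_tc_simulated=isppa_tc_simulated,
    )
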