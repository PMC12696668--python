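"""Seeded synthetic cohort for the TUS-TMS excitability pipeline.

Two generators emulate the data the analysis consumes, so every downstream
stage is testable without participant data:

* :func:`generate_emg_cohort` draws a full trial table (and, optionally,
  waveforms) with the statistical structure of a two-session sham-controlled
  study: 25 trials per measure, four measures (single-pulse, test stimulus,
  SICI, ICF), four timepoints, two conditions, three hand muscles,
  right-skewed (log-normal) peak-to-peak amplitudes centred near 1 mV, and
  injected artefact trials (amplitude outliers, pre-contraction, broadband
  noise) labelled in hidden ground-truth columns.

* :func:`generate_pressure_field` builds a separable Gaussian-ellipsoid
  pressure field whose intensity-FWHM dimensions, anteromedial placement
  bias and in-situ peak intensity are configurable, together with a
  :class:`~tusmep.focus.HeadModel` carrying the brain mask, omega and lip
  landmarks and the 15 mm M1 ROI.

Determinism contract: equal (config, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .dosimetry import pressure_from_isppa
from .focus import HeadModel, Volume

__all__ = [
    "EmgGenConfig",
    "FieldGenConfig",
    "EmgCohort",
    "generate_emg_cohort",
    "generate_pressure_field",
    "generate_cohort_fields",
    "assign_condition_order",
    "generate_masking_noise",
    "original_study_preset",
]

TIMEPOINTS = ("Baseline", "T5", "T30", "T60")
CONDITIONS = ("verum", "sham")
MUSCLES = ("FDI", "APB", "ADM")
PULSE_TYPES = ("single", "TS", "SICI", "ICF")

#: Expected peak-to-peak range of an n-sample standard-normal segment,
#: used by the amplitude-only fast path to stand in for the pre-window
#: peak-to-peak that would be measured on a synthesized waveform.
_GAUSS_PP_FACTOR = 6.9


@dataclass(frozen=True)
class EmgGenConfig:
    """Study-condition defaults for the EMG cohort generator.

    Amplitudes are log-normal: log amp = mep_log_mu + participant effect
    + condition-slope effect + block effect + trial noise, plus log measure
    and condition multipliers.  The defaults are calibrated so the grand
    mean baseline single-pulse amplitude sits in the 1.0-1.1 mV range, SICI
    ~= 0.45 and ICF ~= 1.3 of the test stimulus.
    """

    n_participants: int = 15
    trials_per_block: int = 25
    timepoints: tuple[str, ...] = TIMEPOINTS
    conditions: tuple[str, ...] = CONDITIONS
    muscles: tuple[str, ...] = MUSCLES
    sampling_rate: float = 5000.0  # Hz
    mep_log_mu: float = -0.10  # log mV
    mep_log_sigma: float = 0.45  # trial-level log sd
    participant_log_sd: float = 0.30
    condition_log_sd: float = 0.12  # participant x condition (random slope)
    block_log_sd: float = 0.10  # participant x condition x timepoint
    sici_ratio: float = 0.45
    icf_ratio: float = 1.30
    muscle_scale: tuple[float, ...] = (1.0, 0.8, 0.8)  # follows `muscles`
    condition_effect: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TIMEPOINTS})
    outlier_rate: float = 0.016
    precontraction_rate: float = 0.018
    noise_rate: float = 0.0055
    baseline_emg_rms: float = 0.008  # mV, resting pre-stimulus RMS
    precontraction_rms_multiplier: float = 15.0  # ~0.1 mV: voluntary activity
    noise_artifact_rms: float = 0.18  # mV, broadband contamination
    pre_window_ms: float = 120.0  # pre-stimulus samples in each waveform
    waveform_ms: float = 250.0
    mep_onset_ms: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "precontraction_rate", "noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mep_log_sigma <= 0:
            raise ValueError("mep_log_sigma must be positive")
        if self.n_participants < 1 or self.trials_per_block < 1:
            raise ValueError("counts must be positive")
        for name in ("timepoints", "conditions", "muscles"):
            labels = getattr(self, name)
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} labels must be unique")
        if len(self.muscle_scale) != len(self.muscles):
            raise ValueError("muscle_scale must match muscles")
        if self.pre_window_ms < 100.0:
            raise ValueError("waveforms need >=100 ms of pre-stimulus data")

    @property
    def stimulus_sample(self) -> int:
        return int(round(self.pre_window_ms * self.sampling_rate / 1000.0))

    @property
    def n_samples(self) -> int:
        return int(round(self.waveform_ms * self.sampling_rate / 1000.0))


def original_study_preset(**overrides) -> EmgGenConfig:
    """Facilitation regime of the originally reported protocol.

    Verum MEPs are boosted ~1.4x at T5/T30 with partial decay at T60,
    emulating an excitatory after-effect outlasting sonication; used for
    power/recovery simulations.
    """
    effect = {"Baseline": 1.0, "T5": 1.4, "T30": 1.4, "T60": 1.2}
    return EmgGenConfig(condition_effect=effect, **overrides)


@dataclass
class EmgCohort:
    """Trial table plus optional waveform store.

    ``trials`` carries one row per trial and muscle channel with measured
    quantities (mep_pp, pre_rms, pre_pp) and hidden ground-truth columns
    (amp_true, pre_rms_true, is_outlier_gt, is_precontraction_gt,
    is_noise_gt).  ``waveforms[i]`` is the voltage trace (mV) for table row
    i, or None when only the amplitude table was generated.
    """

    trials: pd.DataFrame
    waveforms: np.ndarray | None
    config: EmgGenConfig

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    @property
    def stimulus_sample(self) -> int:
        return self.config.stimulus_sample


def assign_condition_order(n_participants: int, seed: int) -> pd.DataFrame:
    """Counterbalanced session order: verum-first vs sham-first.

    The two orders differ in count by at most one; for odd n the extra
    participant's order is drawn at random.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    half = n_participants // 2
    orders = ["verum_first"] * half + ["sham_first"] * half
    if n_participants % 2:
        orders.append(rng.choice(["verum_first", "sham_first"]))
    orders = list(rng.permutation(orders))
    rows = []
    for p, order in enumerate(orders):
        s1, s2 = (("verum", "sham") if order == "verum_first"
                  else ("sham", "verum"))
        rows.append({"participant": p, "order": order,
                     "session1": s1, "session2": s2})
    return pd.DataFrame(rows)


def generate_masking_noise(
    duration_s: float, sampling_rate: float, seed: int, amplitude: float = 1.0
) -> np.ndarray:
    """Gaussian white auditory masking noise, i.i.d. N(0, amplitude**2)."""
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    return amplitude * rng.standard_normal(n)


def _mep_template(config: EmgGenConfig) -> np.ndarray:
    """Unit peak-to-peak biphasic deflection starting at the MEP onset.

    Shape: one cycle of a sine under a Gaussian envelope; only the
    peak-to-peak amplitude matters downstream.
    """
    sr = config.sampling_rate
    t = np.arange(config.n_samples) / sr * 1000.0  # ms
    onset = config.pre_window_ms + config.mep_onset_ms
    dur = 18.0  # ms, biphasic wave duration
    centre = onset + dur / 2.0
    envelope = np.exp(-0.5 * ((t - centre) / (dur / 4.0)) ** 2)
    wave = envelope * np.sin(2.0 * np.pi * (t - onset) / dur)
    wave[t < onset] = 0.0
    ptp = wave.max() - wave.min()
    return wave / ptp


def _emg_band_noise(rng: np.random.Generator, shape: tuple, sr: float) -> np.ndarray:
    """Unit-RMS surface-EMG-like noise, band-limited to 20-450 Hz."""
    white = rng.standard_normal(shape)
    sos = sp_signal.butter(2, [20.0, min(450.0, 0.45 * sr)], btype="bandpass",
                           fs=sr, output="sos")
    shaped = sp_signal.sosfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(shaped ** 2, axis=-1, keepdims=True))
    return shaped / np.maximum(rms, 1e-12)


def generate_emg_cohort(
    config: EmgGenConfig | None = None, waveforms: bool = True
) -> EmgCohort:
    """Draw the full synthetic trial table (optionally with waveforms).

    With ``waveforms=False`` the measured columns (mep_pp, pre_rms, pre_pp)
    are filled from the generative model directly — the fast path for
    Monte-Carlo studies of the table-level pipeline.  With waveforms, the
    same quantities are re-measured from the synthesized traces by
    :func:`tusmep.emg.measure_cohort`.
    """
    cfg = config or EmgGenConfig()
    rng = np.random.default_rng(cfg.seed)

    P, K = cfg.n_participants, cfg.trials_per_block
    tps, conds, muscles = cfg.timepoints, cfg.conditions, cfg.muscles
    log_measure = {"single": 0.0, "TS": 0.0,
                   "SICI": float(np.log(cfg.sici_ratio)),
                   "ICF": float(np.log(cfg.icf_ratio))}
    log_muscle = dict(zip(muscles, np.log(np.asarray(cfg.muscle_scale))))

    u_participant = rng.normal(0.0, cfg.participant_log_sd, size=P)
    v_cond = rng.normal(0.0, cfg.condition_log_sd, size=(P, len(conds)))
    w_block = rng.normal(0.0, cfg.block_log_sd,
                         size=(P, len(conds), len(tps)))

    order = assign_condition_order(P, int(rng.integers(0, 2**31)))

    rows: dict[str, list] = {k: [] for k in (
        "participant", "condition", "timepoint", "muscle", "pulse_type",
        "amp_true", "is_outlier_gt", "is_precontraction_gt", "is_noise_gt")}
    eps_store = []
    for p in range(P):
        for ci, cond in enumerate(conds):
            for ti, tp in enumerate(tps):
                for pt in PULSE_TYPES:
                    effect = (np.log(cfg.condition_effect.get(tp, 1.0))
                              if cond == "verum" else 0.0)
                    base = (cfg.mep_log_mu + u_participant[p] + v_cond[p, ci]
                            + w_block[p, ci, ti] + log_measure[pt] + effect)
                    eps = rng.normal(0.0, cfg.mep_log_sigma, size=K)
                    art = rng.random(K)
                    is_out = art < cfg.outlier_rate
                    is_pre = (~is_out) & (art < cfg.outlier_rate
                                          + cfg.precontraction_rate)
                    is_noise = (~is_out) & (~is_pre) & (
                        art < cfg.outlier_rate + cfg.precontraction_rate
                        + cfg.noise_rate)
                    out_factor = rng.uniform(4.0, 8.0, K)
                    for m in muscles:
                        amp = np.exp(base + log_muscle[m] + eps)
                        # outliers are multiples of the block-typical
                        # amplitude (electrode/stimulator artefacts), not of
                        # the trial's own draw, so they always stand out
                        amp = np.where(
                            is_out,
                            np.exp(base + log_muscle[m] + 0.2 * eps) * out_factor,
                            amp)
                        rows["participant"].extend([p] * K)
                        rows["condition"].extend([cond] * K)
                        rows["timepoint"].extend([tp] * K)
                        rows["muscle"].extend([m] * K)
                        rows["pulse_type"].extend([pt] * K)
                        rows["amp_true"].extend(amp.tolist())
                        rows["is_outlier_gt"].extend(is_out.tolist())
                        rows["is_precontraction_gt"].extend(is_pre.tolist())
                        rows["is_noise_gt"].extend(is_noise.tolist())
                        eps_store.append(eps)

    df = pd.DataFrame(rows)
    n = len(df)
    df.insert(0, "trial_id", np.arange(n))
    df["acq_block"] = np.where(df["pulse_type"] == "single", "single", "paired")
    df = df.merge(order[["participant", "order"]], on="participant")
    df["session"] = np.where(
        (df["order"] == "verum_first") == (df["condition"] == "verum"), 1, 2)
    df = df.drop(columns="order")

    # pre-stimulus RMS: log-normal around the resting level, inflated for
    # injected pre-contraction trials; broadband artefact adds in quadrature
    pre_rms = cfg.baseline_emg_rms * np.exp(rng.normal(0.0, 0.2, size=n))
    pre_mult = np.where(df["is_precontraction_gt"],
                        rng.uniform(0.8, 1.5, size=n)
                        * cfg.precontraction_rms_multiplier, 1.0)
    pre_rms = pre_rms * pre_mult
    pre_rms = np.sqrt(pre_rms**2
                      + np.where(df["is_noise_gt"], cfg.noise_artifact_rms, 0.0)**2)
    df["pre_rms_true"] = pre_rms

    if not waveforms:
        df["pre_rms"] = df["pre_rms_true"]
        df["pre_pp"] = _GAUSS_PP_FACTOR * df["pre_rms"]
        noise_pp = _GAUSS_PP_FACTOR * np.where(
            df["is_noise_gt"], cfg.noise_artifact_rms, 0.0)
        df["mep_pp"] = np.maximum(df["amp_true"], noise_pp)
        return EmgCohort(trials=df, waveforms=None, config=cfg)

    template = _mep_template(cfg)
    stim = cfg.stimulus_sample
    wf = np.empty((n, cfg.n_samples), dtype=np.float32)
    base_noise = _emg_band_noise(rng, (n, cfg.n_samples), cfg.sampling_rate)
    # scale the pre-stimulus segment to the target RMS exactly; keep the
    # same per-trial scale after the stimulus so the noise floor is smooth
    seg_rms = np.sqrt(np.mean(base_noise[:, :stim] ** 2, axis=1, keepdims=True))
    scale = (df["pre_rms_true"].to_numpy()[:, None]
             * np.where(df["is_noise_gt"].to_numpy()[:, None], 0.0, 1.0)
             / np.maximum(seg_rms, 1e-12))
    wf[:] = base_noise * scale
    # pre-contraction is confined to the pre-stimulus window: after the
    # stimulus the trace falls back to the resting noise floor
    idx = df["is_precontraction_gt"].to_numpy()
    if idx.any():
        post = np.arange(cfg.n_samples) >= stim
        resting_scale = (cfg.baseline_emg_rms
                         / np.maximum(seg_rms[idx], 1e-12))
        wf[np.ix_(idx, post)] = base_noise[idx][:, post] * resting_scale
    # broadband artefact trials: contamination over the whole sweep
    idx = df["is_noise_gt"].to_numpy()
    if idx.any():
        art = _emg_band_noise(rng, (int(idx.sum()), cfg.n_samples),
                              cfg.sampling_rate)
        resting = cfg.baseline_emg_rms * rng.standard_normal(
            (int(idx.sum()), cfg.n_samples))
        wf[idx] = cfg.noise_artifact_rms * art + resting
    wf += df["amp_true"].to_numpy()[:, None] * template[None, :]

    from .emg import measure_cohort  # deferred: emg does not import synthetic

    cohort = EmgCohort(trials=df, waveforms=wf, config=cfg)
    cohort.trials = measure_cohort(cohort)
    return cohort


@dataclass(frozen=True)
class FieldGenConfig:
    """Gaussian-ellipsoid acoustic field with anteromedial placement jitter.

    ``placement_bias`` and ``placement_sd`` are expressed on (medial,
    anterior, superior) axes; the medial direction is resolved from the
    hemisphere of ``target_point`` (toward x = 0).  The focal dimensions are
    intensity FWHMs.  The in-situ peak Isppa (W/cm**2) is drawn from a
    truncated normal (>= min_isppa).
    """

    grid_shape: tuple[int, int, int] = (101, 101, 101)
    spacing: float = 1.0  # mm, isotropic
    target_point: tuple[float, float, float] = (-38.0, -22.0, 54.0)
    focus_fwhm: tuple[float, float, float] = (6.0, 6.0, 30.0)
    placement_bias: tuple[float, float, float] = (9.5, 10.5, 0.0)
    placement_sd: tuple[float, float, float] = (5.0, 14.2, 7.0)
    peak_insitu_isppa: float = 1.20
    peak_insitu_isppa_sd: float = 0.43
    min_isppa: float = 0.05
    omega_depth: float = 30.0  # mm scalp-to-cortex
    lip_depth: float = 18.0
    skull_scalp_thickness: float = 8.0  # mm between scalp and brain surface
    m1_radius: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(f <= 0 for f in self.focus_fwhm):
            raise ValueError("focus FWHM must be positive")
        if self.peak_insitu_isppa <= 0:
            raise ValueError("peak in-situ Isppa must be positive")
        extent = (np.asarray(self.grid_shape) - 1) * self.spacing
        if any(f > e for f, e in zip(self.focus_fwhm, extent)):
            raise ValueError("focus FWHM exceeds grid extent")


def _grid_affine(cfg: FieldGenConfig) -> np.ndarray:
    """RAS affine centring the grid on the target point."""
    shape = np.asarray(cfg.grid_shape)
    origin = np.asarray(cfg.target_point) - cfg.spacing * (shape - 1) / 2.0
    aff = np.eye(4)
    aff[:3, :3] *= cfg.spacing
    aff[:3, 3] = origin
    return aff


def _head_model(cfg: FieldGenConfig, affine: np.ndarray) -> HeadModel:
    omega = np.asarray(cfg.target_point, dtype=float)
    scalp_z = omega[2] + cfg.omega_depth
    lip = omega.copy()
    lip[2] = scalp_z - cfg.lip_depth
    brain_top = scalp_z - cfg.skull_scalp_thickness
    shape = cfg.grid_shape
    probe = Volume(values=np.zeros(shape, dtype=np.uint8), affine=affine)
    _, _, gz = probe.world_grids()
    mask = Volume(values=(gz <= brain_top), affine=affine)
    return HeadModel(brain_mask=mask, omega=omega, lip=lip,
                     m1_radius=cfg.m1_radius)


def generate_pressure_field(
    config: FieldGenConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, HeadModel]:
    """One participant's pressure field (Pa) and head model.

    The intensity field is a separable Gaussian whose peak sits at the
    target plus the (hemisphere-resolved) placement bias plus per-axis
    normal jitter, snapped to the nearest voxel centre and clipped half a
    FWHM inside the grid and below the brain surface.
    """
    cfg = config or FieldGenConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    affine = _grid_affine(cfg)
    head = _head_model(cfg, affine)

    target = np.asarray(cfg.target_point, dtype=float)
    medial_sign = 1.0 if target[0] < 0 else -1.0
    bias = np.asarray(cfg.placement_bias, dtype=float)
    sd = np.asarray(cfg.placement_sd, dtype=float)
    shift = bias + np.where(sd > 0, rng.normal(0.0, np.maximum(sd, 1e-12)), 0.0)
    shift_world = shift * np.array([medial_sign, 1.0, 1.0])
    peak = target + shift_world

    # keep the peak inside the grid (half a FWHM margin) and inside the brain
    fwhm = np.asarray(cfg.focus_fwhm, dtype=float)
    shape = np.asarray(cfg.grid_shape)
    lo = affine[:3, 3] + fwhm / 2.0
    hi = affine[:3, 3] + cfg.spacing * (shape - 1) - fwhm / 2.0
    brain_top = target[2] + cfg.omega_depth - cfg.skull_scalp_thickness
    hi[2] = min(hi[2], brain_top - cfg.spacing)
    peak = np.clip(peak, lo, hi)

    # snap to the nearest voxel centre so the stored maximum is exact
    probe = Volume(values=np.zeros((1, 1, 1)), affine=affine)
    peak = probe.voxel_to_world(np.round(probe.world_to_voxel(peak)))

    if cfg.peak_insitu_isppa_sd > 0:
        a = (cfg.min_isppa - cfg.peak_insitu_isppa) / cfg.peak_insitu_isppa_sd
        peak_isppa = float(stats.truncnorm.ppf(
            rng.random(), a, np.inf,
            loc=cfg.peak_insitu_isppa, scale=cfg.peak_insitu_isppa_sd))
    else:
        peak_isppa = cfg.peak_insitu_isppa

    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    axes = [affine[a, 3] + cfg.spacing * np.arange(cfg.grid_shape[a])
            for a in range(3)]
    g = [np.exp(-0.5 * ((ax - peak[a]) / sigma[a]) ** 2)
         for a, ax in enumerate(axes)]
    intensity = peak_isppa * (g[0][:, None, None] * g[1][None, :, None]
                              * g[2][None, None, :])
    pressure = pressure_from_isppa(intensity)
    return Volume(values=pressure, affine=affine), head


def generate_cohort_fields(
    config: FieldGenConfig | None = None, n_participants: int = 15
) -> list[tuple[Volume, HeadModel]]:
    """Independent pressure fields for a cohort, from one master seed."""
    cfg = config or FieldGenConfig()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(n_participants):
        sub = np.random.default_rng(int(rng.integers(0, 2**31)))
        out.append(generate_pressure_field(cfg, rng=sub))
    return out
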