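"""Acoustic-focus targeting metrics on 3D intensity volumes.

The acoustic focus is the set of voxels whose pulse-average intensity is at
least half of the intensity maximum inside the brain (the full-width
half-maximum volume).  Targeting accuracy is quantified by the overlap of
this focus with a spherical M1 region of interest, and by Euclidean
distances from the intensity peak to two precentral-gyrus landmarks: the
omega formation (hand knob, ~30 mm scalp-to-cortex depth) and the gyral
lip/crown (~18 mm).

Coordinate convention (used package-wide): world coordinates are RAS+
millimetres — +x right, +y anterior, +z superior.  For a left-hemisphere
target (x < 0) "medial" is +x; for a right-hemisphere target it is -x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import stats

from .dosimetry import AcousticConstants, isppa_from_pressure

__all__ = [
    "Volume",
    "HeadModel",
    "FocusReport",
    "intensity_volume_from_pressure",
    "in_brain_peak",
    "fwhm_focus",
    "roi_overlap",
    "landmark_distances",
    "axis_shift",
    "group_axis_tests",
    "group_focus_map",
    "compute_focus_report",
    "measure_axis_fwhm",
]


@dataclass
class Volume:
    """A 3D scalar field on a regular grid with a voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three grid axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm**3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if xyz.shape[0] == 1 else xyz

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return ijk[0] if ijk.shape[0] == 1 else ijk

    def world_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate of every voxel centre, one array per world axis."""
        idx = np.indices(self.values.shape, dtype=float)
        R, t = self.affine[:3, :3], self.affine[:3, 3]
        out = [R[a, 0] * idx[0] + R[a, 1] * idx[1] + R[a, 2] * idx[2] + t[a]
               for a in range(3)]
        return out[0], out[1], out[2]

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.values.astype(np.uint8) if self.values.dtype == bool \
            else self.values.astype(np.float32)
        return nib.Nifti1Image(data, self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, as_mask: bool = False) -> "Volume":
        data = np.asanyarray(img.dataobj)
        if as_mask:
            data = data > 0
        return cls(values=data, affine=np.asarray(img.affine))


@dataclass
class HeadModel:
    """Brain mask plus the landmarks that define the M1 target geometry.

    ``m1_center`` defaults to the midpoint of the omega and lip landmarks so
    that the 15 mm sphere covers both.
    """

    brain_mask: Volume
    omega: np.ndarray  # world mm, hand-knob seed, ~30 mm depth
    lip: np.ndarray  # world mm, gyral lip/crown, ~18 mm depth
    m1_radius: float = 15.0
    m1_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.lip = np.asarray(self.lip, dtype=float)
        if self.m1_radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.m1_center is None:
            self.m1_center = 0.5 * (self.omega + self.lip)
        else:
            self.m1_center = np.asarray(self.m1_center, dtype=float)

    def roi_mask(self, like: Volume) -> np.ndarray:
        """Boolean mask of the spherical M1 ROI on the grid of ``like``."""
        gx, gy, gz = like.world_grids()
        d2 = ((gx - self.m1_center[0]) ** 2 + (gy - self.m1_center[1]) ** 2
              + (gz - self.m1_center[2]) ** 2)
        return d2 <= self.m1_radius ** 2


@dataclass
class FocusReport:
    """Per-participant targeting metrics."""

    peak_loc: np.ndarray  # world mm
    peak_isppa: float  # W/cm**2, in-brain maximum
    focus_volume_mm3: float
    overlap_pct: float
    roi_peak_isppa: float
    dist_omega: float  # mm
    dist_lip: float  # mm
    axis_shift: np.ndarray  # (medial+, anterior+, superior+) mm, vs omega
    focus_mask: Volume | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "peak_loc_mm": [float(v) for v in self.peak_loc],
            "peak_isppa_w_cm2": float(self.peak_isppa),
            "focus_volume_mm3": float(self.focus_volume_mm3),
            "overlap_pct": float(self.overlap_pct),
            "roi_peak_isppa_w_cm2": float(self.roi_peak_isppa),
            "dist_omega_mm": float(self.dist_omega),
            "dist_lip_mm": float(self.dist_lip),
            "axis_shift_mm": {
                "medial": float(self.axis_shift[0]),
                "anterior": float(self.axis_shift[1]),
                "superior": float(self.axis_shift[2]),
            },
        }


def intensity_volume_from_pressure(
    pressure: Volume, constants: AcousticConstants = AcousticConstants()
) -> Volume:
    """Voxel-wise plane-wave conversion, Pa -> W/cm**2."""
    vals = isppa_from_pressure(np.abs(pressure.values), constants)
    return Volume(values=vals, affine=pressure.affine.copy())


def in_brain_peak(intensity: Volume, brain_mask: Volume) -> tuple[np.ndarray, float]:
    """(world location, value) of the intensity maximum inside the brain.

    Ties are broken by the lowest linear voxel index (C order).
    """
    mask = brain_mask.values.astype(bool)
    if intensity.values.shape != mask.shape:
        raise ValueError("intensity and brain mask grids differ")
    if not mask.any():
        raise ValueError("brain mask is empty")
    vals = np.where(mask, intensity.values, -np.inf)
    flat = int(np.argmax(vals))  # argmax returns the first (lowest) maximiser
    ijk = np.unravel_index(flat, vals.shape)
    return intensity.voxel_to_world(np.array(ijk, dtype=float)), float(vals[ijk])


def fwhm_focus(intensity: Volume, brain_mask: Volume) -> tuple[Volume, float]:
    """FWHM acoustic focus: voxels with I >= half the in-brain maximum.

    Voxels exactly at half-maximum are included.  The focus is restricted to
    the brain mask; no connected-component filtering is applied.
    """
    _, peak = in_brain_peak(intensity, brain_mask)
    if peak <= 0:
        raise ValueError("in-brain intensity maximum must be positive")
    mask = (intensity.values >= 0.5 * peak) & brain_mask.values.astype(bool)
    focus = Volume(values=mask, affine=intensity.affine.copy())
    return focus, float(mask.sum()) * intensity.voxel_volume


def roi_overlap(
    focus_mask: Volume, roi_mask: np.ndarray, intensity: Volume
) -> tuple[float, float]:
    """(% of focus volume inside the ROI, peak intensity inside the ROI)."""
    fm = focus_mask.values.astype(bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if fm.shape != roi.shape or fm.shape != intensity.values.shape:
        raise ValueError("focus, ROI and intensity grids differ")
    n_focus = int(fm.sum())
    if n_focus == 0:
        raise ValueError("focus mask is empty")
    overlap = 100.0 * int((fm & roi).sum()) / n_focus
    roi_peak = float(intensity.values[roi].max()) if roi.any() else float("nan")
    return overlap, roi_peak


def axis_shift(peak_loc, omega) -> np.ndarray:
    """Signed (medial+, anterior+, superior+) displacement of the peak, mm.

    The medial sign follows the hemisphere of the omega landmark: toward the
    midline (x = 0) is positive.
    """
    peak_loc = np.asarray(peak_loc, dtype=float)
    omega = np.asarray(omega, dtype=float)
    d = peak_loc - omega
    medial_sign = 1.0 if omega[0] < 0 else -1.0
    return np.array([medial_sign * d[0], d[1], d[2]])


def landmark_distances(peak_loc, head_model: HeadModel) -> dict:
    """Euclidean distances (mm) to omega and lip, plus the axis shift."""
    peak_loc = np.asarray(peak_loc, dtype=float)
    return {
        "dist_omega": float(np.linalg.norm(peak_loc - head_model.omega)),
        "dist_lip": float(np.linalg.norm(peak_loc - head_model.lip)),
        "axis_shift": axis_shift(peak_loc, head_model.omega),
    }


def group_axis_tests(shifts: np.ndarray) -> list[dict]:
    """Two-sided one-sample t-test against zero per axis.

    ``shifts`` is (n_participants, 3) in (medial, anterior, superior) order.
    Zero-variance axes with nonzero mean are reported with p = 0 and a flag.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.ndim != 2 or shifts.shape[1] != 3:
        raise ValueError("shifts must be (n, 3)")
    n = shifts.shape[0]
    if n < 2:
        raise ValueError("need at least two participants per axis")
    out = []
    for a, name in enumerate(("medial", "anterior", "superior")):
        x = shifts[:, a]
        sd = x.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            t = 0.0 if x.mean() == 0 else np.inf * np.sign(x.mean())
            p = 1.0 if x.mean() == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(x, 0.0)
        out.append({
            "axis": name, "mean": float(x.mean()), "sd": float(sd),
            "t": float(t), "df": n - 1, "p": float(p),
            "zero_variance": bool(degenerate),
        })
    return out


def group_focus_map(focus_masks: list[Volume]) -> Volume:
    """Voxel-wise count of overlapping binary focus masks on a shared grid."""
    if not focus_masks:
        raise ValueError("no focus masks given")
    ref = focus_masks[0]
    acc = np.zeros(ref.values.shape, dtype=np.int32)
    for fm in focus_masks:
        if fm.values.shape != ref.values.shape or not np.allclose(fm.affine, ref.affine):
            raise ValueError("focus masks are not on a common grid")
        acc += fm.values.astype(bool)
    return Volume(values=acc, affine=ref.affine.copy())


def compute_focus_report(
    intensity: Volume, head_model: HeadModel, keep_mask: bool = True
) -> FocusReport:
    """Full per-participant targeting report from one intensity volume."""
    peak_loc, peak_val = in_brain_peak(intensity, head_model.brain_mask)
    focus, vol = fwhm_focus(intensity, head_model.brain_mask)
    roi = head_model.roi_mask(intensity)
    overlap, roi_peak = roi_overlap(focus, roi, intensity)
    dists = landmark_distances(peak_loc, head_model)
    return FocusReport(
        peak_loc=peak_loc,
        peak_isppa=peak_val,
        focus_volume_mm3=vol,
        overlap_pct=overlap,
        roi_peak_isppa=roi_peak,
        dist_omega=dists["dist_omega"],
        dist_lip=dists["dist_lip"],
        axis_shift=dists["axis_shift"],
        focus_mask=focus if keep_mask else None,
    )


def measure_axis_fwhm(intensity: Volume, axis: int) -> float:
    """FWHM (mm) of the 1D intensity profile through the global peak.

    Linear interpolation between the voxels bracketing the half-maximum
    crossings; used to validate generated fields against their configured
    focal dimensions.
    """
    ijk = np.unravel_index(int(np.argmax(intensity.values)), intensity.values.shape)
    sl = list(ijk)
    sl[axis] = slice(None)
    profile = intensity.values[tuple(sl)].astype(float)
    half = profile.max() / 2.0
    above = np.nonzero(profile >= half)[0]
    lo, hi = above[0], above[-1]

    def _interp(i_in: int, i_out: int) -> float:
        if i_out < 0 or i_out >= profile.size:
            return float(i_in)
        f = (profile[i_in] - half) / (profile[i_in] - profile[i_out])
        return i_in + f * (i_out - i_in)

    left = _interp(lo, lo - 1)
    right = _interp(hi, hi + 1)
    return float((right - left) * intensity.spacing[axis])
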