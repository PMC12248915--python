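"""Parametric map computation from dynamic ^13C series.

Three source maps are derived per voxel: the pyruvate-to-lactate
conversion rate k_PL from an inputless two-site exchange fit, the
pyruvate signal summed over time (AUC), and the mean pyruvate time (MT,
the center of mass of the pyruvate signal-time curve). Maps are then
resampled to a 5 mm isotropic analysis grid.

The inputless fit uses the measured pyruvate signal itself as the source
term, so no arterial input function is needed. Given a fixed lactate
relaxation time and the frame-level trapezoidal recursion, the predicted
lactate curve is linear in k_PL, and the bounded least-squares estimate
has a closed form (the normal-equation solution clipped to the bounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.processing import resample_to_output

from .cohort import AcquisitionConfig, PatientImaging

__all__ = [
    "DynamicSeries",
    "KineticModelConfig",
    "ParametricMapSet",
    "fit_kpl_inputless",
    "compute_pyr_auc",
    "compute_mean_time",
    "compute_maps",
    "resample_maps",
    "save_map_set",
    "load_map_set",
]

logger = logging.getLogger(__name__)


@dataclass
class DynamicSeries:
    """4D dynamic pyruvate/lactate signal pair on a common grid."""

    pyr_signal: np.ndarray   # (x, y, z, frame)
    lac_signal: np.ndarray
    acq: AcquisitionConfig
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.pyr_signal.shape != self.lac_signal.shape:
            raise ValueError("pyruvate and lactate series must share shape")
        if self.pyr_signal.shape[-1] != self.acq.n_frames:
            raise ValueError("frame count must match acquisition config")

    @classmethod
    def from_patient(cls, pt: PatientImaging) -> "DynamicSeries":
        return cls(pt.pyr, pt.lac, pt.acq, pt.affine)


@dataclass(frozen=True)
class KineticModelConfig:
    """Configuration of the inputless k_PL fit.

    ``t1l_seconds`` is the fixed effective lactate T1 (not fitted);
    ``kpl_bounds_per_second`` bounds the estimate; ``solver_tolerance``
    guards the normal-equation denominator against degeneracy.
    """

    t1l_seconds: float = 25.0
    kpl_bounds_per_second: tuple[float, float] = (0.0, 0.1)
    solver_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        lo, hi = self.kpl_bounds_per_second
        if not (0 <= lo < hi):
            raise ValueError("kpl bounds must satisfy 0 <= lower < upper")
        if self.t1l_seconds <= 0 or self.solver_tolerance <= 0:
            raise ValueError("t1l_seconds and solver_tolerance must be positive")


@dataclass
class ParametricMapSet:
    """Co-registered k_PL / pyruvate-AUC / mean-time maps plus lesion mask.

    ``kpl_map`` is in ks^-1 (1e-3 s^-1); ``mean_time_map`` in seconds;
    ``pyr_auc_map`` in the series' arbitrary signal units.
    """

    kpl_map: np.ndarray
    pyr_auc_map: np.ndarray
    mean_time_map: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.kpl_map.shape, self.pyr_auc_map.shape,
            self.mean_time_map.shape, self.mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all maps and the mask must share one grid")

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0


def _background_sigma(first_frame: np.ndarray) -> float:
    """Robust noise scale from the first frame (bolus not yet arrived)."""
    v = first_frame.reshape(-1)
    med = np.median(v)
    return float(1.4826 * np.median(np.abs(v - med)))


def fit_kpl_inputless(
    series: DynamicSeries, model: KineticModelConfig | None = None
) -> np.ndarray:
    """Voxelwise inputless two-site exchange k_PL fit, in ks^-1.

    Signals are converted to magnetizations (divide by sin of the flip
    angle), the lactate state is seeded from the first measured lactate
    frame, and the frame recursion

        L[i+1] = L[i] * cos(th_L) * exp(-TR/T1L)
                 + kpl * TR * (P[i]*cos(th_P) + P[i+1]) / 2

    is propagated with the measured pyruvate as the source. The returned
    k_PL minimizes the sum of squared lactate-signal residuals over the
    configured bounds. Voxels whose pyruvate peak sits below the noise
    floor (3x the robust first-frame background SD) return 0; non-finite
    voxels are zeroed and counted in a log record.
    """
    if model is None:
        model = KineticModelConfig()
    acq = series.acq
    tr = acq.tr_seconds
    sin_p = np.sin(np.deg2rad(acq.flip_pyr_degrees))
    sin_l = np.sin(np.deg2rad(acq.flip_lac_degrees))
    cos_p = np.cos(np.deg2rad(acq.flip_pyr_degrees))
    cos_l = np.cos(np.deg2rad(acq.flip_lac_degrees))
    a = cos_l * np.exp(-tr / model.t1l_seconds)

    shape3 = series.pyr_signal.shape[:3]
    sp = series.pyr_signal.reshape(-1, acq.n_frames).astype(float)
    sl = series.lac_signal.reshape(-1, acq.n_frames).astype(float)

    bad = ~(np.isfinite(sp).all(axis=1) & np.isfinite(sl).all(axis=1))
    if bad.any():
        logger.warning("fit_kpl_inputless: %d non-finite voxels zeroed", int(bad.sum()))
        sp[bad] = 0.0
        sl[bad] = 0.0

    floor = 3.0 * _background_sigma(series.pyr_signal[..., 0])
    fit_vox = sp.max(axis=1) > floor

    P = sp[fit_vox] / sin_p          # measured pyruvate magnetization
    Lm = sl[fit_vox] / sin_l         # measured lactate magnetization
    nfit, T = P.shape
    kpl = np.zeros(sp.shape[0])
    if nfit:
        b = tr * (P[:, :-1] * cos_p + P[:, 1:]) / 2.0
        # homogeneous part: measured first lactate frame decaying freely
        powers = a ** np.arange(T)
        h = Lm[:, [0]] * powers[None, :]
        # kpl-coefficient curve c: c[0]=0, c[i+1] = a*c[i] + b[i]
        c = np.zeros_like(P)
        for i in range(T - 1):
            c[:, i + 1] = a * c[:, i] + b[:, i]
        resid = Lm - h
        num = (resid[:, 1:] * c[:, 1:]).sum(axis=1)
        den = (c[:, 1:] ** 2).sum(axis=1)
        est = np.zeros(nfit)
        ok = den > model.solver_tolerance * max(1.0, float(np.abs(resid).max()) ** 2)
        est[ok] = num[ok] / den[ok]
        lo, hi = model.kpl_bounds_per_second
        kpl[fit_vox] = np.clip(est, lo, hi)
    return (kpl * 1000.0).reshape(shape3)


def compute_pyr_auc(series: DynamicSeries) -> np.ndarray:
    """Pyruvate signal summed over frames (no TR scaling)."""
    return series.pyr_signal.sum(axis=-1)


def compute_mean_time(series: DynamicSeries) -> np.ndarray:
    """Center of mass of the pyruvate signal-time curve, in seconds.

    Voxels whose summed pyruvate signal does not exceed the noise floor
    (3x robust background SD, scaled by sqrt(n_frames) for the sum)
    return 0.
    """
    t = series.acq.frame_times
    s = series.pyr_signal
    total = s.sum(axis=-1)
    floor = 3.0 * _background_sigma(s[..., 0]) * np.sqrt(series.acq.n_frames)
    mt = np.zeros(total.shape)
    good = total > max(floor, 0.0)
    if good.any():
        mt[good] = (s[good] * t).sum(axis=-1) / total[good]
    np.clip(mt, 0.0, t[-1], out=mt)
    return mt


def compute_maps(
    series: DynamicSeries,
    mask: np.ndarray,
    model: KineticModelConfig | None = None,
) -> ParametricMapSet:
    """All three source maps on the native grid."""
    return ParametricMapSet(
        kpl_map=fit_kpl_inputless(series, model),
        pyr_auc_map=compute_pyr_auc(series),
        mean_time_map=compute_mean_time(series),
        mask=np.asarray(mask),
        affine=series.affine,
    )


def resample_maps(
    maps: ParametricMapSet, voxel_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
) -> ParametricMapSet:
    """Resample maps to an isotropic analysis grid covering the FOV.

    Intensity maps use trilinear interpolation; the integer label mask
    uses nearest-neighbor.
    """
    if abs(np.linalg.det(maps.affine)) < 1e-12:
        raise ValueError("singular affine")

    def _res(arr: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), maps.affine)
        out = resample_to_output(img, voxel_sizes=voxel_mm, order=order, cval=0.0)
        return np.asarray(out.dataobj), out.affine

    kpl, aff = _res(maps.kpl_map, 1)
    auc, _ = _res(maps.pyr_auc_map, 1)
    mt, _ = _res(maps.mean_time_map, 1)
    mk, _ = _res(maps.mask.astype(np.float64), 0)
    return ParametricMapSet(
        kpl_map=np.clip(kpl, 0.0, None),
        pyr_auc_map=auc,
        mean_time_map=np.clip(mt, 0.0, None),
        mask=np.round(mk).astype(np.int16),
        affine=aff,
    )


def save_map_set(maps: ParametricMapSet, out_dir: str | Path, prefix: str) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr, dtype in (
        ("kpl", maps.kpl_map, np.float32),
        ("pyr_auc", maps.pyr_auc_map, np.float32),
        ("mean_time", maps.mean_time_map, np.float32),
        ("mask", maps.mask, np.int16),
    ):
        p = out / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(dtype), maps.affine), p)
        paths[name] = p
    return paths


def load_map_set(out_dir: str | Path, prefix: str) -> ParametricMapSet:
    out = Path(out_dir)

    def _load(name: str) -> tuple[np.ndarray, np.ndarray]:
        img = nib.load(out / f"{prefix}_{name}.nii.gz")
        return np.asarray(img.dataobj), img.affine

    kpl, aff = _load("kpl")
    auc, _ = _load("pyr_auc")
    mt, _ = _load("mean_time")
    mk, _ = _load("mask")
    return ParametricMapSet(
        kpl_map=np.asarray(kpl, float),
        pyr_auc_map=np.asarray(auc, float),
        mean_time_map=np.asarray(mt, float),
        mask=np.asarray(mk).astype(np.int16),
        affine=aff,
    )
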