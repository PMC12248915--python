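"""Multiparametric features of metabolism (MFM) from parametric maps.

For each patient, the three resampled metabolic maps (k_PL, pyruvate
AUC, mean pyruvate time) are restricted to the lesion mask and reduced
to a named scalar feature vector: an 18-feature first-order set per map,
a shape elongation per map (identical values, per-map labels), the
GLDM/GLRLM/GLSZM texture scalar sets per map, and the total metabolic
volume (TMV, lesion volume with measurable k_PL).

Feature names follow the ``<map>_original_<class>_<Feature>`` convention
(e.g. ``kPL_original_firstorder_90Percentile``).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import ParametricMapSet
from .texture import build_gray_level_matrix, texture_features

__all__ = [
    "DiscretizationConfig",
    "discretize",
    "first_order_features",
    "shape_elongation",
    "total_metabolic_volume",
    "extract_patient_features",
    "cohort_feature_matrix",
    "MAP_NAMES",
]

logger = logging.getLogger(__name__)

#: map key -> (attribute on ParametricMapSet, feature-name prefix)
MAP_NAMES = {
    "kPL": "kpl_map",
    "pyrAUC": "pyr_auc_map",
    "MT": "mean_time_map",
}


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed bin widths per map, in each map's native units.

    Defaults: 1.0 ks^-1 for k_PL (equivalently 0.001 s^-1), 0.02 signal
    units for pyruvate AUC (the generator's signals are on a
    fraction-of-delivered-polarization scale, so in-lesion AUC values are
    order 1), and 0.1 s for mean pyruvate time.
    """

    bin_width_by_map: dict[str, float] = field(
        default_factory=lambda: {"kPL": 1.0, "pyrAUC": 0.02, "MT": 0.1}
    )

    def __post_init__(self) -> None:
        if set(self.bin_width_by_map) != set(MAP_NAMES):
            raise ValueError(f"bin widths required for maps {sorted(MAP_NAMES)}")
        if any(w <= 0 for w in self.bin_width_by_map.values()):
            raise ValueError("bin widths must be positive")


def discretize(values: np.ndarray, width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray levels anchored at the ROI minimum.

    level(x) = floor((x - min) / width) + 1, with the maximum value
    clamped into the top bin. Returns (levels, n_gray_levels).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty ROI")
    if width <= 0:
        raise ValueError("bin width must be positive")
    vmin = values.min()
    rng = values.max() - vmin
    n_levels = max(int(math.ceil(rng / width - 1e-9)), 1)
    levels = np.floor((values - vmin) / width).astype(np.int64) + 1
    return np.minimum(levels, n_levels), n_levels


def first_order_features(
    values: np.ndarray,
    levels: np.ndarray | None = None,
    width: float | None = None,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """The 18-feature first-order intensity set of one ROI.

    Entropy and uniformity are computed on the discretized histogram
    (``levels`` may be passed directly, or ``width`` to discretize here).
    Kurtosis is non-excess (a normal distribution scores 3).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty ROI")
    if levels is None:
        levels, _ = discretize(v, width if width is not None else 1.0)
    counts = np.bincount(np.asarray(levels))[1:]
    p = counts[counts > 0] / v.size
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    var = float(v.var())
    with warnings.catch_warnings():
        # near-constant ROIs trigger scipy's precision-loss warning; the
        # degenerate values are substituted below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(stats.skew(v)) if var > 0 else 0.0
        kurt = float(stats.kurtosis(v, fisher=False)) if var > 0 else 1.0
    if not np.isfinite(skew):
        skew = 0.0
    if not np.isfinite(kurt):
        kurt = 1.0
    return {
        "Mean": float(v.mean()),
        "Median": float(p50),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((v ** 2).sum()),
        "TotalEnergy": float((v ** 2).sum() * voxel_volume_mm3),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p ** 2).sum()),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(v.max() - v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(v - v.mean()).mean()),
        # tiny ROIs can leave the 10-90 percentile window empty
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
    }


def shape_elongation(coords_mm: np.ndarray) -> float:
    """sqrt(lambda2 / lambda1) of the voxel-center coordinate covariance.

    lambda1 >= lambda2 are the two largest principal-component
    eigenvalues; a cube scores 1, collinear voxels 0. Degenerate ROIs
    (fewer than two distinct coordinates) return NaN.
    """
    c = np.asarray(coords_mm, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords_mm must be (n, 3)")
    if c.shape[0] < 2 or np.allclose(c, c[0]):
        return float("nan")
    lam = np.sort(np.linalg.eigvalsh(np.cov(c.T)))[::-1]
    if lam[0] <= 0:
        return float("nan")
    return float(np.sqrt(max(lam[1], 0.0) / lam[0]))


def total_metabolic_volume(maps: ParametricMapSet) -> float:
    """Lesion volume (mL) with measurable (positive) k_PL."""
    qualifying = (maps.mask > 0) & (maps.kpl_map > 0)
    return float(qualifying.sum()) * maps.voxel_volume_ml


def _roi_coords_mm(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _single_roi_features(
    maps: ParametricMapSet,
    roi: np.ndarray,
    disc: DiscretizationConfig,
) -> dict[str, float]:
    feats: dict[str, float] = {}
    vox_mm3 = maps.voxel_volume_ml * 1000.0
    elong = shape_elongation(_roi_coords_mm(roi, maps.affine))
    for map_key, attr in MAP_NAMES.items():
        vals = getattr(maps, attr)[roi]
        width = disc.bin_width_by_map[map_key]
        levels, n_levels = discretize(vals, width)
        fo = first_order_features(vals, levels=levels, voxel_volume_mm3=vox_mm3)
        for name, val in fo.items():
            feats[f"{map_key}_original_firstorder_{name}"] = val
        feats[f"{map_key}_original_shape_Elongation"] = elong
        grid = np.zeros(roi.shape, dtype=np.int64)
        grid[roi] = levels
        for kind, cls in (("GLDM", "gldm"), ("GLRLM", "glrlm"), ("GLSZM", "glszm")):
            glm = build_gray_level_matrix(grid, roi, kind, n_gray_levels=n_levels)
            for name, val in texture_features(glm).items():
                feats[f"{map_key}_original_{cls}_{name}"] = val
    return feats


def extract_patient_features(
    maps: ParametricMapSet,
    disc: DiscretizationConfig | None = None,
    mode: str = "merged",
) -> dict[str, float]:
    """Named MFM vector for one patient.

    ``mode="merged"`` (default) pools all lesion labels into one
    composite ROI; ``mode="per_lesion"`` extracts per lesion label and
    averages weighted by lesion voxel count (TMV is summed either way).
    Raises ValueError if the mask contains no lesion.
    """
    if disc is None:
        disc = DiscretizationConfig()
    if not (maps.mask > 0).any():
        raise ValueError("no lesions in mask")
    if mode == "merged":
        feats = _single_roi_features(maps, maps.mask > 0, disc)
    elif mode == "per_lesion":
        labels = np.unique(maps.mask[maps.mask > 0])
        per = []
        weights = []
        for lab in labels:
            roi = maps.mask == lab
            per.append(_single_roi_features(maps, roi, disc))
            weights.append(float(roi.sum()))
        w = np.array(weights) / sum(weights)
        feats = {
            name: float(np.nansum([wi * d[name] for wi, d in zip(w, per)]))
            for name in per[0]
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    feats["TMV"] = total_metabolic_volume(maps)
    return feats


def cohort_feature_matrix(
    patient_maps: dict[str, ParametricMapSet],
    disc: DiscretizationConfig | None = None,
    mode: str = "merged",
) -> pd.DataFrame:
    """Feature matrix (rows = patients, columns = feature names).

    Patients whose mask holds no lesion are dropped with a warning.
    """
    rows = {}
    for pid, maps in patient_maps.items():
        try:
            rows[pid] = extract_patient_features(maps, disc, mode)
        except ValueError as exc:
            logger.warning("patient %s excluded: %s", pid, exc)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "patient_id"
    return df
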