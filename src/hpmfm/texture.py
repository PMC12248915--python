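"""Gray-level texture matrices and their scalar features.

Implements the three higher-order texture families used for the
metabolic parametric maps: the gray-level run length matrix (GLRLM,
runs of equal level along the 13 unique 3D directions, aggregated by
matrix summation), the gray-level size zone matrix (GLSZM, 26-connected
equal-level zones by size), and the gray-level dependence matrix (GLDM,
per-voxel count of 26-neighbors sharing the voxel's level, tolerance 0).

Conventions, fixed for reproducibility:

* gray levels are positive integers 1..Ng from fixed-bin-width
  discretization anchored at the ROI minimum;
* GLDM "dependence size" j counts the center voxel plus its dependent
  neighbors, so j ranges 1..27 and small-dependence emphasis is finite;
* run/zone/dependence scalar features follow the standardized
  radiomics formulas (16 GLRLM, 16 GLSZM, 14 GLDM scalars).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GrayLevelMatrix", "build_gray_level_matrix", "texture_features"]

_EPS = np.finfo(float).tiny


@dataclass
class GrayLevelMatrix:
    kind: str                # "GLDM" | "GLRLM" | "GLSZM"
    matrix: np.ndarray       # (n_gray_levels, size axis) integer counts
    n_gray_levels: int
    n_voxels: int            # in-mask voxel count

    def __post_init__(self) -> None:
        if self.kind not in ("GLDM", "GLRLM", "GLSZM"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if (self.matrix < 0).any():
            raise ValueError("counts must be nonnegative")


# 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """arr shifted so that out[v] = arr[v + d], zero-filled at borders."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for ax, step in enumerate(d):
        n = arr.shape[ax]
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(step, n))
            dst.append(slice(0, n - step))
        else:
            src.append(slice(0, n + step))
            dst.append(slice(-step, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def _build_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum of per-direction run-length matrices over the 13 directions."""
    lv = np.where(mask, levels, 0)
    max_len = max(lv.shape)
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    for d in DIRECTIONS_3D:
        nxt = _shift(lv, d)
        same_next = mask & (nxt == lv) & (nxt > 0)
        # run length remaining from each voxel (dynamic programming)
        run = mask.astype(np.int64)
        for _ in range(max_len - 1):
            stepped = np.where(same_next, 1 + _shift(run, d), mask.astype(np.int64))
            if np.array_equal(stepped, run):
                break
            run = stepped
        prev_same = _shift(same_next, tuple(-x for x in d))
        starts = mask & ~prev_same
        np.add.at(counts, (lv[starts] - 1, run[starts] - 1), 1)
    return counts[:, : counts.any(axis=0).nonzero()[0].max() + 1]


def _run_groups(sorted_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, start indices, run lengths) of a sorted 1D array."""
    starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    counts = np.diff(np.r_[starts, sorted_vals.size])
    return sorted_vals[starts], starts, counts


def _build_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """26-connected zones of equal level, counted by zone size.

    Each gray level is labeled inside its own bounding box only.
    """
    struct = np.ones((3, 3, 3), dtype=bool)
    lv = np.where(mask, levels, 0)
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    coords = np.argwhere(lv > 0)
    vals = lv[tuple(coords.T)]
    order = np.argsort(vals, kind="stable")
    coords, vals = coords[order], vals[order]
    for g, start, count in zip(*_run_groups(vals)):
        pts = coords[start : start + count]
        lo = pts.min(axis=0)
        sub = np.zeros(pts.max(axis=0) - lo + 1, dtype=bool)
        sub[tuple((pts - lo).T)] = True
        lab, n = ndimage.label(sub, structure=struct)
        sizes = np.bincount(lab.reshape(-1))[1:]
        for s in sizes:
            zone_counts[(int(g), int(s))] = zone_counts.get((int(g), int(s)), 0) + 1
            max_size = max(max_size, int(s))
    counts = np.zeros((n_levels, max_size), dtype=np.int64)
    for (g, s), c in zone_counts.items():
        counts[g - 1, s - 1] = c
    return counts


def _build_gldm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: 26-neighbors with the identical level."""
    lv = np.where(mask, levels, 0)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS_3D:
        for dd in (d, tuple(-x for x in d)):
            nxt = _shift(lv, dd)
            dep += (mask & (nxt == lv) & (nxt > 0)).astype(np.int64)
    counts = np.zeros((n_levels, 27), dtype=np.int64)
    np.add.at(counts, (lv[mask] - 1, dep[mask]), 1)
    return counts[:, : counts.any(axis=0).nonzero()[0].max() + 1]


def build_gray_level_matrix(
    levels: np.ndarray, mask: np.ndarray, kind: str, n_gray_levels: int | None = None
) -> GrayLevelMatrix:
    """Build one texture matrix from a discretized 3D level grid.

    ``levels`` holds integer gray levels >= 1 at in-mask voxels (values
    outside ``mask`` are ignored). For GLDM the returned size axis is the
    dependent-neighbor count (0-based column k = k dependent neighbors);
    scalar features use the dependence size j = k + 1.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.ndim != 3 or mask.shape != levels.shape:
        raise ValueError("levels and mask must be matching 3D arrays")
    if not mask.any():
        raise ValueError("empty mask")
    if (levels[mask] < 1).any():
        raise ValueError("in-mask levels must be >= 1")
    n = int(n_gray_levels if n_gray_levels is not None else levels[mask].max())
    lv, mk = _crop_to_mask(levels, mask)
    builders = {"GLRLM": _build_glrlm, "GLSZM": _build_glszm, "GLDM": _build_gldm}
    if kind not in builders:
        raise ValueError(f"unknown matrix kind {kind!r}")
    counts = builders[kind](lv, mk, n)
    return GrayLevelMatrix(kind=kind, matrix=counts, n_gray_levels=n,
                           n_voxels=int(mk.sum()))


# ---------------------------------------------------------------------------
# scalar features


def _common(glm: GrayLevelMatrix, j_offset: int) -> dict:
    P = glm.matrix.astype(float)
    Ns = P.sum()
    if Ns == 0:
        raise ValueError("all-zero matrix")
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = (np.arange(P.shape[1], dtype=float) + j_offset)[None, :]
    p = P / Ns
    return {"P": P, "p": p, "Ns": Ns, "i": i, "j": j}


def _emphases(P, Ns, i, j) -> dict[str, float]:
    return {
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Ns),
        "GrayLevelVariance": _wvar(P / Ns, i),
        "LowGrayLevel": float((P / i ** 2).sum() / Ns),
        "HighGrayLevel": float((P * i ** 2).sum() / Ns),
        "SmallLow": float((P / (i ** 2 * j ** 2)).sum() / Ns),
        "SmallHigh": float((P * i ** 2 / j ** 2).sum() / Ns),
        "LargeLow": float((P * j ** 2 / i ** 2).sum() / Ns),
        "LargeHigh": float((P * i ** 2 * j ** 2).sum() / Ns),
        "Small": float((P / j ** 2).sum() / Ns),
        "Large": float((P * j ** 2).sum() / Ns),
        "SizeNonUniformity": float((P.sum(axis=0) ** 2).sum() / Ns),
        "SizeVariance": _wvar(P / Ns, j),
        "Entropy": float(-(P / Ns * np.log2(P / Ns + _EPS))[P > 0].sum()),
    }


def _wvar(p: np.ndarray, vals: np.ndarray) -> float:
    mu = (p * vals).sum()
    return float((p * (vals - mu) ** 2).sum())


def texture_features(glm: GrayLevelMatrix) -> dict[str, float]:
    """Scalar feature set of one gray-level matrix.

    Returns 16 features for GLRLM/GLSZM and 14 for GLDM, keyed by their
    conventional radiomics names (without the class prefix).
    """
    # size axis: column c holds run length / zone size / dependence size
    # j = c + 1 (GLDM columns store dependent-neighbor counts k = j - 1)
    c = _common(glm, j_offset=1.0)
    P, Ns, i, j = c["P"], c["Ns"], c["i"], c["j"]
    e = _emphases(P, Ns, i, j)
    nv = glm.n_voxels

    if glm.kind == "GLRLM":
        # runs cover each voxel once per direction
        coverage = float((P * j).sum())
        return {
            "ShortRunEmphasis": e["Small"],
            "LongRunEmphasis": e["Large"],
            "GrayLevelNonUniformity": e["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": e["GrayLevelNonUniformity"] / Ns,
            "RunLengthNonUniformity": e["SizeNonUniformity"],
            "RunLengthNonUniformityNormalized": e["SizeNonUniformity"] / Ns,
            "RunPercentage": float(Ns / coverage),
            "GrayLevelVariance": e["GrayLevelVariance"],
            "RunVariance": e["SizeVariance"],
            "RunEntropy": e["Entropy"],
            "LowGrayLevelRunEmphasis": e["LowGrayLevel"],
            "HighGrayLevelRunEmphasis": e["HighGrayLevel"],
            "ShortRunLowGrayLevelEmphasis": e["SmallLow"],
            "ShortRunHighGrayLevelEmphasis": e["SmallHigh"],
            "LongRunLowGrayLevelEmphasis": e["LargeLow"],
            "LongRunHighGrayLevelEmphasis": e["LargeHigh"],
        }
    if glm.kind == "GLSZM":
        return {
            "SmallAreaEmphasis": e["Small"],
            "LargeAreaEmphasis": e["Large"],
            "GrayLevelNonUniformity": e["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": e["GrayLevelNonUniformity"] / Ns,
            "SizeZoneNonUniformity": e["SizeNonUniformity"],
            "SizeZoneNonUniformityNormalized": e["SizeNonUniformity"] / Ns,
            "ZonePercentage": float(Ns / nv),
            "GrayLevelVariance": e["GrayLevelVariance"],
            "ZoneVariance": e["SizeVariance"],
            "ZoneEntropy": e["Entropy"],
            "LowGrayLevelZoneEmphasis": e["LowGrayLevel"],
            "HighGrayLevelZoneEmphasis": e["HighGrayLevel"],
            "SmallAreaLowGrayLevelEmphasis": e["SmallLow"],
            "SmallAreaHighGrayLevelEmphasis": e["SmallHigh"],
            "LargeAreaLowGrayLevelEmphasis": e["LargeLow"],
            "LargeAreaHighGrayLevelEmphasis": e["LargeHigh"],
        }
    # GLDM: one entry per voxel, Ns == n_voxels
    return {
        "SmallDependenceEmphasis": e["Small"],
        "LargeDependenceEmphasis": e["Large"],
        "GrayLevelNonUniformity": e["GrayLevelNonUniformity"],
        "DependenceNonUniformity": e["SizeNonUniformity"],
        "DependenceNonUniformityNormalized": e["SizeNonUniformity"] / Ns,
        "GrayLevelVariance": e["GrayLevelVariance"],
        "DependenceVariance": e["SizeVariance"],
        "DependenceEntropy": e["Entropy"],
        "LowGrayLevelEmphasis": e["LowGrayLevel"],
        "HighGrayLevelEmphasis": e["HighGrayLevel"],
        "SmallDependenceLowGrayLevelEmphasis": e["SmallLow"],
        "SmallDependenceHighGrayLevelEmphasis": e["SmallHigh"],
        "LargeDependenceLowGrayLevelEmphasis": e["LargeLow"],
        "LargeDependenceHighGrayLevelEmphasis": e["LargeHigh"],
    }
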