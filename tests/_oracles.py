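"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops,
no vectorization, no reuse of package internals) so that agreement with
the package implementations is a meaningful check.
"""

from collections import deque

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glrlm_bruteforce(levels, mask, n_levels):
    """Runs of equal level along 13 directions, enumerated voxel by voxel."""
    shape = levels.shape
    entries = {}
    for d in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    v = (x, y, z)
                    if not mask[v]:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if (
                        _inside(shape, prev)
                        and mask[prev]
                        and levels[prev] == levels[v]
                    ):
                        continue  # not a run start
                    length = 1
                    cur = v
                    while True:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if (
                            _inside(shape, nxt)
                            and mask[nxt]
                            and levels[nxt] == levels[v]
                        ):
                            length += 1
                            cur = nxt
                        else:
                            break
                    key = (int(levels[v]), length)
                    entries[key] = entries.get(key, 0) + 1
    max_len = max((l for (_, l) in entries), default=1)
    out = np.zeros((n_levels, max_len), dtype=np.int64)
    for (g, l), c in entries.items():
        out[g - 1, l - 1] = c
    return out


def glszm_bruteforce(levels, mask, n_levels):
    """26-connected equal-level zones found by breadth-first search."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    entries = {}
    max_size = 1
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = (x, y, z)
                if not mask[v] or seen[v]:
                    continue
                g = int(levels[v])
                q = deque([v])
                seen[v] = True
                size = 0
                while q:
                    cur = q.popleft()
                    size += 1
                    for d in NEIGHBORS_26:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if (
                            _inside(shape, nxt)
                            and mask[nxt]
                            and not seen[nxt]
                            and int(levels[nxt]) == g
                        ):
                            seen[nxt] = True
                            q.append(nxt)
                entries[(g, size)] = entries.get((g, size), 0) + 1
                max_size = max(max_size, size)
    out = np.zeros((n_levels, max_size), dtype=np.int64)
    for (g, s), c in entries.items():
        out[g - 1, s - 1] = c
    return out


def gldm_bruteforce(levels, mask, n_levels):
    """Per-voxel count of equal-level 26-neighbors (tolerance 0)."""
    shape = levels.shape
    entries = {}
    max_dep = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = (x, y, z)
                if not mask[v]:
                    continue
                dep = 0
                for d in NEIGHBORS_26:
                    nxt = (x + d[0], y + d[1], z + d[2])
                    if (
                        _inside(shape, nxt)
                        and mask[nxt]
                        and levels[nxt] == levels[v]
                    ):
                        dep += 1
                entries[(int(levels[v]), dep)] = entries.get((int(levels[v]), dep), 0) + 1
                max_dep = max(max_dep, dep)
    out = np.zeros((n_levels, max_dep + 1), dtype=np.int64)
    for (g, k), c in entries.items():
        out[g - 1, k] = c
    return out


def texture_scalars_bruteforce(kind, matrix, n_voxels):
    """Direct double-loop evaluation of the scalar texture formulas."""
    P = np.asarray(matrix, dtype=float)
    Ns = P.sum()
    ni, nj = P.shape
    sums = {k: 0.0 for k in (
        "sj2", "lj2", "li2", "hi2", "sl", "sh", "ll", "lh", "cov", "ent"
    )}
    mu_i = mu_j = 0.0
    for a in range(ni):
        for b in range(nj):
            p = P[a, b] / Ns
            mu_i += p * (a + 1)
            mu_j += p * (b + 1)
    var_i = var_j = 0.0
    for a in range(ni):
        i = a + 1.0
        for b in range(nj):
            j = b + 1.0
            c = P[a, b]
            p = c / Ns
            sums["sj2"] += c / j ** 2
            sums["lj2"] += c * j ** 2
            sums["li2"] += c / i ** 2
            sums["hi2"] += c * i ** 2
            sums["sl"] += c / (i ** 2 * j ** 2)
            sums["sh"] += c * i ** 2 / j ** 2
            sums["ll"] += c * j ** 2 / i ** 2
            sums["lh"] += c * i ** 2 * j ** 2
            sums["cov"] += c * j
            var_i += p * (i - mu_i) ** 2
            var_j += p * (j - mu_j) ** 2
            if c > 0:
                sums["ent"] -= p * np.log2(p)
    row = [float(P[a, :].sum()) for a in range(ni)]
    col = [float(P[:, b].sum()) for b in range(nj)]
    gln = sum(r ** 2 for r in row) / Ns
    szn = sum(c ** 2 for c in col) / Ns
    common = {
        "small": sums["sj2"] / Ns,
        "large": sums["lj2"] / Ns,
        "low": sums["li2"] / Ns,
        "high": sums["hi2"] / Ns,
        "small_low": sums["sl"] / Ns,
        "small_high": sums["sh"] / Ns,
        "large_low": sums["ll"] / Ns,
        "large_high": sums["lh"] / Ns,
        "gln": gln,
        "szn": szn,
        "glv": var_i,
        "szv": var_j,
        "entropy": sums["ent"],
    }
    if kind == "GLRLM":
        return {
            "ShortRunEmphasis": common["small"],
            "LongRunEmphasis": common["large"],
            "GrayLevelNonUniformity": common["gln"],
            "GrayLevelNonUniformityNormalized": common["gln"] / Ns,
            "RunLengthNonUniformity": common["szn"],
            "RunLengthNonUniformityNormalized": common["szn"] / Ns,
            "RunPercentage": Ns / sums["cov"],
            "GrayLevelVariance": common["glv"],
            "RunVariance": common["szv"],
            "RunEntropy": common["entropy"],
            "LowGrayLevelRunEmphasis": common["low"],
            "HighGrayLevelRunEmphasis": common["high"],
            "ShortRunLowGrayLevelEmphasis": common["small_low"],
            "ShortRunHighGrayLevelEmphasis": common["small_high"],
            "LongRunLowGrayLevelEmphasis": common["large_low"],
            "LongRunHighGrayLevelEmphasis": common["large_high"],
        }
    if kind == "GLSZM":
        return {
            "SmallAreaEmphasis": common["small"],
            "LargeAreaEmphasis": common["large"],
            "GrayLevelNonUniformity": common["gln"],
            "GrayLevelNonUniformityNormalized": common["gln"] / Ns,
            "SizeZoneNonUniformity": common["szn"],
            "SizeZoneNonUniformityNormalized": common["szn"] / Ns,
            "ZonePercentage": Ns / n_voxels,
            "GrayLevelVariance": common["glv"],
            "ZoneVariance": common["szv"],
            "ZoneEntropy": common["entropy"],
            "LowGrayLevelZoneEmphasis": common["low"],
            "HighGrayLevelZoneEmphasis": common["high"],
            "SmallAreaLowGrayLevelEmphasis": common["small_low"],
            "SmallAreaHighGrayLevelEmphasis": common["small_high"],
            "LargeAreaLowGrayLevelEmphasis": common["large_low"],
            "LargeAreaHighGrayLevelEmphasis": common["large_high"],
        }
    return {
        "SmallDependenceEmphasis": common["small"],
        "LargeDependenceEmphasis": common["large"],
        "GrayLevelNonUniformity": common["gln"],
        "DependenceNonUniformity": common["szn"],
        "DependenceNonUniformityNormalized": common["szn"] / Ns,
        "GrayLevelVariance": common["glv"],
        "DependenceVariance": common["szv"],
        "DependenceEntropy": common["entropy"],
        "LowGrayLevelEmphasis": common["low"],
        "HighGrayLevelEmphasis": common["high"],
        "SmallDependenceLowGrayLevelEmphasis": common["small_low"],
        "SmallDependenceHighGrayLevelEmphasis": common["small_high"],
        "LargeDependenceLowGrayLevelEmphasis": common["large_low"],
        "LargeDependenceHighGrayLevelEmphasis": common["large_high"],
    }


def concordance_bruteforce(risk, times, events):
    """O(n^2) pair enumeration of Harrell's C.

    Pair usable iff times strictly differ and the earlier time is an
    observed event; tied risks count 1/2.
    """
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1.0
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        return float("nan")
    return num / den
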