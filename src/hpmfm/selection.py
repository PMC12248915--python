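"""Feature selection and the Metabolic Prognostic Score (MPS).

The multivariate chain: every feature column (metabolic features plus
serology) is scored by an adjusted concordance index — a weighted sum
0.8 * C_PFS + 0.2 * C_OS of the Harrell C of its univariate Cox linear
predictor against each endpoint — the top 20% are retained, retained
features are grouped by average-linkage agglomerative clustering under
the distance 1 - |Pearson r|, one representative (the top scorer) is
kept per cluster, and a multivariate Cox model on the representatives
plus patient age yields the MPS: a linear risk score whose cohort median
dichotomizes patients into lower-risk and higher-risk groups (lower MPS
is favorable). Leave-one-out refits quantify coefficient stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .survival import CoxFit, KMCurve, cox_fit, impute_alp, km_by_group

__all__ = [
    "SelectionConfig",
    "MpsModel",
    "LooStability",
    "adjusted_c_index",
    "rank_and_retain",
    "cluster_and_select",
    "build_mps",
    "mps_score",
    "loo_stability",
    "correlogram",
]


@dataclass(frozen=True)
class SelectionConfig:
    w_pfs: float = 0.8
    w_os: float = 0.2
    retain_fraction: float = 0.20
    n_clusters: int = 4
    serology_features: tuple[str, ...] = ("psa", "ldh", "alp")

    def __post_init__(self) -> None:
        if abs(self.w_pfs + self.w_os - 1.0) > 1e-12:
            raise ValueError("w_pfs + w_os must equal 1")
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must lie in (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")


def _endpoint(clinical: pd.DataFrame, which: str) -> tuple[np.ndarray, np.ndarray]:
    return (
        clinical[f"{which}_months"].to_numpy(dtype=float),
        clinical[f"{which}_event"].to_numpy(dtype=int),
    )


def adjusted_c_index(
    feature: pd.Series | np.ndarray,
    clinical: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> float:
    """Weighted univariate concordance w_pfs * C_PFS + w_os * C_OS.

    Each C is the Harrell C of the fitted univariate Cox linear
    predictor, which self-orients the feature's sign (C >= 0.5).
    Degenerate (constant) features return NaN.
    """
    if cfg is None:
        cfg = SelectionConfig()
    x = pd.DataFrame({"f": np.asarray(feature, dtype=float)})
    if x["f"].std(ddof=0) == 0 or not np.isfinite(x["f"]).all():
        return float("nan")
    cs = {}
    for ep in ("pfs", "os"):
        t, e = _endpoint(clinical, ep)
        cs[ep] = cox_fit(x, t, e).c_index
    return cfg.w_pfs * cs["pfs"] + cfg.w_os * cs["os"]


@dataclass
class RankingResult:
    scores: pd.Series           # adjusted C per feature (NaN-dropped)
    retained: list[str]
    matrix: pd.DataFrame        # feature matrix incl. serology columns


def rank_and_retain(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> RankingResult:
    """Score all features and keep the top ``retain_fraction`` by rank.

    Serology columns from the clinical table (ALP median-imputed) are
    appended to the metabolic feature matrix before scoring. The
    retention count is ceil(fraction * feature count); ties in score
    break deterministically by feature name.
    """
    if cfg is None:
        cfg = SelectionConfig()
    clin = impute_alp(clinical).set_index("patient_id").loc[feature_matrix.index]
    mat = feature_matrix.copy()
    for s in cfg.serology_features:
        mat[s] = clin[s].to_numpy(dtype=float)
    clin = clin.reset_index()
    scores = {}
    for col in mat.columns:
        c = adjusted_c_index(mat[col], clin, cfg)
        if not math.isnan(c):
            scores[col] = c
    if not scores:
        raise ValueError("all features degenerate; nothing to rank")
    s = pd.Series(scores)
    n_keep = int(math.ceil(cfg.retain_fraction * mat.shape[1]))
    order = sorted(s.index, key=lambda name: (-s[name], name))
    retained = order[: min(n_keep, len(order))]
    return RankingResult(scores=s, retained=retained, matrix=mat)


@dataclass
class ClusterResult:
    representatives: list[str]
    assignments: dict[str, int]          # feature -> cluster id (1-based)
    correlogram: pd.DataFrame            # leaf-ordered Pearson r matrix
    linkage: np.ndarray


def cluster_and_select(
    retained_matrix: pd.DataFrame,
    scores: pd.Series,
    cfg: SelectionConfig | None = None,
) -> ClusterResult:
    """Correlation-distance agglomerative clustering + per-cluster pick.

    Distance d(f, g) = 1 - |Pearson r(f, g)| across patients;
    average-linkage dendrogram cut into ``n_clusters`` branches; from
    each cluster the member with the highest adjusted C-index (name as
    tie-break) is selected. The leaf-ordered correlation matrix is
    returned for correlogram rendering.
    """
    if cfg is None:
        cfg = SelectionConfig()
    cols = list(retained_matrix.columns)
    if len(cols) < cfg.n_clusters:
        raise ValueError(
            f"{len(cols)} retained features < n_clusters={cfg.n_clusters}"
        )
    X = retained_matrix.to_numpy(dtype=float)
    r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    d = np.clip(1.0 - np.abs(r), 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cfg.n_clusters, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(Z)
    corr = pd.DataFrame(r, index=cols, columns=cols)
    corr = corr.iloc[leaf_order, leaf_order]
    reps = []
    for k in sorted(set(labels)):
        members = [cols[i] for i in np.flatnonzero(labels == k)]
        members.sort(key=lambda name: (-scores.get(name, -np.inf), name))
        reps.append(members[0])
    return ClusterResult(
        representatives=reps,
        assignments={c: int(k) for c, k in zip(cols, labels)},
        correlogram=corr,
        linkage=Z,
    )


def mps_score(
    coefficients: dict[str, float], values: dict[str, float] | pd.DataFrame
) -> float | np.ndarray:
    """Pure linear score: sum of coefficient * covariate value."""
    names = list(coefficients)
    w = np.array([coefficients[n] for n in names], dtype=float)
    if isinstance(values, pd.DataFrame):
        return values[names].to_numpy(dtype=float) @ w
    x = np.array([values[n] for n in names], dtype=float)
    return float(x @ w)


@dataclass
class MpsModel:
    """Fitted Metabolic Prognostic Score.

    ``coefficients`` are the PFS Cox log-hazard weights of the selected
    representatives plus age; ``threshold`` is the training-cohort median
    score; lower scores indicate more favorable prognosis.
    """

    selected_features: list[str]
    coefficients: dict[str, float]
    threshold: float
    scores: pd.Series
    pfs_fit: CoxFit
    os_fit: CoxFit
    km_pfs: dict[str, KMCurve | None]
    km_os: dict[str, KMCurve | None]
    ridge_stabilized: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def lrt_p(self) -> dict[str, float]:
        return {"pfs": self.pfs_fit.lrt_p, "os": self.os_fit.lrt_p}

    @property
    def c_index(self) -> dict[str, float]:
        return {"pfs": self.pfs_fit.c_index, "os": self.os_fit.c_index}


_CONDITION_LIMIT = 1e8
_RIDGE_FALLBACK = 1e-2


def _fit_mps_cox(X: pd.DataFrame, t: np.ndarray, e: np.ndarray) -> tuple[CoxFit, bool, list[str]]:
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    cond = np.linalg.cond((Xv - Xv.mean(axis=0)) / sd)
    warns: list[str] = []
    if cond > _CONDITION_LIMIT:
        warns.append(
            f"collinear representatives (condition number {cond:.3g}); "
            "ridge-stabilized refit"
        )
        return cox_fit(X, t, e, ridge=_RIDGE_FALLBACK), True, warns
    return cox_fit(X, t, e), False, warns


def build_mps(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    representatives: list[str],
    cfg: SelectionConfig | None = None,
) -> MpsModel:
    """Fit the age-adjusted multivariate Cox model and assemble the MPS.

    The model is fitted on the PFS endpoint; the resulting linear score
    is evaluated against OS through a univariate Cox fit of the score.
    The dichotomization threshold is the cohort median score.
    """
    clin = impute_alp(clinical).set_index("patient_id").loc[feature_matrix.index]
    X = pd.DataFrame(index=feature_matrix.index)
    for name in representatives:
        if name in feature_matrix.columns:
            X[name] = feature_matrix[name].astype(float)
        elif name in clin.columns:
            X[name] = clin[name].astype(float)
        else:
            raise KeyError(f"representative {name!r} not found")
    X["age"] = clin["age"].astype(float)
    t_pfs, e_pfs = clin["pfs_months"].to_numpy(), clin["pfs_event"].to_numpy(int)
    t_os, e_os = clin["os_months"].to_numpy(), clin["os_event"].to_numpy(int)

    fit, ridged, warns = _fit_mps_cox(X, t_pfs, e_pfs)
    coefficients = dict(zip(fit.names, fit.beta))
    scores = pd.Series(mps_score(coefficients, X), index=X.index, name="mps")
    threshold = float(scores.median())
    os_fit = cox_fit(pd.DataFrame({"mps": scores}), t_os, e_os)
    return MpsModel(
        selected_features=list(representatives),
        coefficients=coefficients,
        threshold=threshold,
        scores=scores,
        pfs_fit=fit,
        os_fit=os_fit,
        km_pfs=km_by_group(scores.to_numpy(), threshold, t_pfs, e_pfs),
        km_os=km_by_group(scores.to_numpy(), threshold, t_os, e_os),
        ridge_stabilized=ridged,
        warnings=warns + fit.warnings,
    )


@dataclass
class LooStability:
    coefficients: pd.DataFrame      # one row per leave-one-out refit
    normalized_sd: dict[str, float]
    n_refits: int
    n_failures: int
    failed_patients: list[str]


def loo_stability(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    representatives: list[str],
    cfg: SelectionConfig | None = None,
) -> LooStability:
    """Leave-one-patient-out coefficient stability of the MPS model.

    For each of the n patients the model is refitted on the remaining
    n-1; the per-coefficient SD across refits divided by the absolute
    full-cohort coefficient is the normalized SD.
    """
    if feature_matrix.shape[0] < 3:
        raise ValueError("need at least 3 patients for leave-one-out")
    full = build_mps(feature_matrix, clinical, representatives, cfg)
    rows = {}
    failed: list[str] = []
    for pid in feature_matrix.index:
        sub_feat = feature_matrix.drop(index=pid)
        sub_clin = clinical[clinical["patient_id"] != pid]
        try:
            m = build_mps(sub_feat, sub_clin, representatives, cfg)
            rows[pid] = m.coefficients
        except Exception:  # refit failure flagged, not fatal
            failed.append(pid)
    coefs = pd.DataFrame.from_dict(rows, orient="index")
    norm_sd = {}
    for name in coefs.columns:
        sd = float(coefs[name].std(ddof=0))
        ref = abs(full.coefficients[name])
        # zero spread is stable regardless of the reference coefficient
        norm_sd[name] = 0.0 if sd == 0 else (sd / ref if ref > 0 else float("nan"))
    return LooStability(
        coefficients=coefs,
        normalized_sd=norm_sd,
        n_refits=len(rows),
        n_failures=len(failed),
        failed_patients=failed,
    )


def correlogram(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    columns: list[str] | None = None,
    cfg: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Symmetric Pearson correlation table of features vs outcomes.

    Correlates the chosen feature columns plus serology against the
    observed PFS/OS durations (censored durations included as observed,
    a documented approximation). Zero-variance columns yield NaN.
    """
    if cfg is None:
        cfg = SelectionConfig()
    clin = impute_alp(clinical).set_index("patient_id").loc[feature_matrix.index]
    cols = columns if columns is not None else list(feature_matrix.columns)
    tab = pd.DataFrame(index=feature_matrix.index)
    for c in cols:
        tab[c] = feature_matrix[c].astype(float)
    for s in cfg.serology_features:
        if s not in tab.columns:
            tab[s] = clin[s].astype(float)
    tab["PFS"] = clin["pfs_months"].astype(float)
    tab["OS"] = clin["os_months"].astype(float)
    return tab.corr(method="pearson")
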