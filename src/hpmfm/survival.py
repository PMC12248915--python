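"""Survival-analysis machinery: Cox PH, Harrell's C, Kaplan-Meier.

The working container for patient-level outcomes is a pandas DataFrame
with the clinical-table schema (``patient_id, age, psa, ldh, alp,
pfs_months, pfs_event, os_months, os_event``; event 1 = observed,
0 = censored).

The Cox partial likelihood is maximized by Newton-Raphson with Breslow
tie handling to a gradient-norm tolerance of 1e-8; the likelihood-ratio
test against the null model provides p-values, and the inverse observed
information the coefficient covariance. Harrell's concordance counts a
patient pair as usable when the two times differ and the earlier time is
an observed event; tied risk scores contribute 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "CoxFit",
    "KMCurve",
    "harrell_c",
    "cox_fit",
    "km_curve",
    "km_by_group",
    "impute_alp",
    "validate_clinical",
]

CLINICAL_COLUMNS = [
    "patient_id", "age", "psa", "ldh", "alp",
    "pfs_months", "pfs_event", "os_months", "os_event",
]

#: cap on standardized coefficient magnitude; beyond it the partial
#: likelihood is treated as monotone (perfect separation)
_BETA_CAP = 30.0


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    for c in ("pfs_months", "os_months"):
        if (df[c] < 0).any():
            raise ValueError(f"{c} must be nonnegative")
    for c in ("pfs_event", "os_event"):
        if not df[c].isin([0, 1]).all():
            raise ValueError(f"{c} must be binary")
    return df


def harrell_c(
    risk_scores: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's concordance index of a risk score against censored times.

    Over all usable pairs (times strictly unequal, earlier time an
    observed event): concordant (higher risk with the shorter time)
    counts 1, tied risk counts 1/2. Returns NaN when no pair is usable.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (r.shape == t.shape == e.shape):
        raise ValueError("risk_scores, times, events must have equal length")
    # pair (i, j) usable iff t_i < t_j and event_i
    earlier = t[:, None] < t[None, :]
    usable = earlier & e[:, None]
    n_usable = usable.sum()
    if n_usable == 0:
        return float("nan")
    conc = usable & (r[:, None] > r[None, :])
    ties = usable & (r[:, None] == r[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_usable)


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    lrt_stat: float
    lrt_p: float
    c_index: float
    n: int
    n_events: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        """Per-covariate HR with Wald 95% CI."""
        z = stats.norm.ppf(0.975)
        with np.errstate(over="ignore"):
            return pd.DataFrame(
                {
                    "HR": np.exp(self.beta),
                    "lower95": np.exp(self.beta - z * self.se),
                    "upper95": np.exp(self.beta + z * self.se),
                },
                index=self.names,
            )

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


def _breslow_loglik(
    b: np.ndarray, X: np.ndarray, order_t: np.ndarray, ev: np.ndarray,
    first_at_risk: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, gradient and Hessian.

    Inputs are pre-sorted by ascending time; ``first_at_risk[i]`` is the
    index of the first subject whose time >= time_i (handles ties: tied
    subjects share one risk set).
    """
    eta = X @ b
    eta -= eta.max()  # overflow guard; cancels in the likelihood
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    # reverse cumulative sums: risk set of subject i is i..n-1 (by first_at_risk)
    W = np.cumsum(w[::-1])[::-1]
    WX = np.cumsum(wx[::-1], axis=0)[::-1]
    WXX = np.cumsum(wxx[::-1], axis=0)[::-1]
    idx = first_at_risk[ev]
    Wd, WXd, WXXd = W[idx], WX[idx], WXX[idx]
    ll = float(eta[ev].sum() - np.log(Wd).sum())
    xbar = WXd / Wd[:, None]
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    hess = -(
        (WXXd / Wd[:, None, None]).sum(axis=0)
        - (xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    )
    return ll, grad, hess


def cox_fit(
    covariates: pd.DataFrame | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    Covariates are standardized internally for numerical stability and
    the estimates mapped back to the original scale. Monotone likelihood
    (perfect separation) is detected as a diverging standardized
    coefficient and reported with a capped estimate and a warning.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X0 = covariates.to_numpy(dtype=float)
    else:
        X0 = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X0.shape[0] == 1 and len(np.asarray(times)) != 1:
            X0 = X0.T
        names = [f"x{i}" for i in range(X0.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    n, p = X0.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("covariates, times, events must align")
    if not np.isfinite(X0).all():
        raise ValueError("missing/non-finite covariates; impute upstream")
    if e.sum() == 0:
        raise ValueError("no observed events")
    mu = X0.mean(axis=0)
    sd = X0.std(axis=0)
    const = sd == 0
    if const.any():
        # constant covariates carry no partial-likelihood information:
        # fit the informative subset and report zero coefficients for the
        # rest (undefined variance)
        keep = ~const
        dropped = [names[i] for i in np.flatnonzero(const)]
        if keep.any():
            sub = cox_fit(
                pd.DataFrame(X0[:, keep], columns=[names[i] for i in np.flatnonzero(keep)]),
                t, e, ridge=ridge, tol=tol, max_iter=max_iter,
            )
            beta = np.zeros(p)
            beta[keep] = sub.beta
            cov = np.full((p, p), np.nan)
            cov[np.ix_(keep, keep)] = sub.covariance
            return CoxFit(
                names=names, beta=beta, covariance=cov,
                loglik=sub.loglik, loglik_null=sub.loglik_null,
                lrt_stat=sub.lrt_stat, lrt_p=sub.lrt_p,
                c_index=sub.c_index, n=n, n_events=int(e.sum()),
                converged=sub.converged,
                warnings=sub.warnings + [f"constant covariate(s) dropped: {dropped}"],
            )
        # every covariate constant: the null model
        ll0, _, _ = _breslow_loglik(
            np.zeros(0), np.zeros((n, 0)),
            np.sort(t), e[np.argsort(t, kind="stable")],
            np.searchsorted(np.sort(t), np.sort(t), side="left"),
        )
        return CoxFit(
            names=names, beta=np.zeros(p), covariance=np.full((p, p), np.nan),
            loglik=ll0, loglik_null=ll0, lrt_stat=0.0, lrt_p=1.0,
            c_index=0.5, n=n, n_events=int(e.sum()), converged=True,
            warnings=[f"all covariates constant: {dropped}; null model returned"],
        )
    X = (X0 - mu) / sd

    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    first_at_risk = np.searchsorted(ts, ts, side="left")

    warns: list[str] = []
    b = np.zeros(p)
    ll0, _, _ = _breslow_loglik(b, Xs, ts, es, first_at_risk)
    ll = ll0
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik(b, Xs, ts, es, first_at_risk)
        if ridge > 0:
            ll -= 0.5 * ridge * float(b @ b)
            grad = grad - ridge * b
            hess = hess - ridge * np.eye(p)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        step = np.linalg.solve(hess, -grad)
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            b_new = b + scale * step
            ll_new, _, _ = _breslow_loglik(b_new, Xs, ts, es, first_at_risk)
            if ridge > 0:
                ll_new -= 0.5 * ridge * float(b_new @ b_new)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        b = b + scale * step
        if np.abs(b).max() > _BETA_CAP:
            warns.append(
                "monotone partial likelihood (perfect separation?); "
                f"standardized coefficients capped at {_BETA_CAP}"
            )
            b = np.clip(b, -_BETA_CAP, _BETA_CAP)
            ll, grad, hess = _breslow_loglik(b, Xs, ts, es, first_at_risk)
            break
    else:
        warns.append("Newton-Raphson did not reach gradient tolerance")

    ll, grad, hess = _breslow_loglik(b, Xs, ts, es, first_at_risk)
    if ridge > 0:
        hess = hess - ridge * np.eye(p)
    try:
        cov_std = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_std = np.full((p, p), np.nan)
        warns.append("singular information matrix")
    D = np.diag(1.0 / sd)
    beta = b / sd
    cov = D @ cov_std @ D

    lrt = max(2.0 * (ll - ll0), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, df=p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c = harrell_c(X0 @ beta, t, e.astype(int))
    return CoxFit(
        names=names, beta=beta, covariance=cov,
        loglik=ll, loglik_null=ll0, lrt_stat=lrt, lrt_p=lrt_p,
        c_index=c, n=n, n_events=int(e.sum()),
        converged=converged, warnings=warns,
    )


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk counts and median survival.

    ``median`` is the smallest time with S(t) <= 0.5, or +inf when the
    curve never reaches 0.5 ("NR", not reached).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int
    n_events: int

    @property
    def median_label(self) -> str:
        return "NR" if np.isinf(self.median) else f"{self.median:g}"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator of one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=at_risk,
        median=med,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def km_by_group(
    scores: np.ndarray,
    threshold: float,
    times: np.ndarray,
    events: np.ndarray,
) -> dict[str, KMCurve | None]:
    """Dichotomized KM curves: "low" = score <= threshold, "high" above.

    An empty group maps to None.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    out: dict[str, KMCurve | None] = {}
    for name, sel in (("low", s <= threshold), ("high", s > threshold)):
        out[name] = km_curve(t[sel], e[sel]) if sel.any() else None
    return out


def impute_alp(clinical: pd.DataFrame) -> pd.DataFrame:
    """Replace missing ALP readings with the cohort median of observed ALP."""
    observed = clinical["alp"].dropna()
    if observed.empty:
        raise ValueError("all ALP values missing; cannot impute")
    out = clinical.copy()
    out["alp"] = out["alp"].fillna(float(observed.median()))
    return out
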