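"""Synthetic hyperpolarized ^13C-pyruvate MRI cohort generation.

Emulates the data structure of a small advanced-prostate-cancer imaging
study: per-patient 4D dynamic pyruvate/lactate series on a coarse native
EPI grid, 3D integer lesion-label masks, and a linked clinical table
(age, serology, progression-free and overall survival with censoring).

The dynamic signal follows a discrete two-site exchange recursion driven
by a gamma-variate bolus; survival times follow a Weibull-baseline
proportional-hazards law whose linear predictor is built from the
generator-side ground-truth imaging features, so downstream feature
ranking and risk-score construction have a known signal to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.special import gammainc

__all__ = [
    "AcquisitionConfig",
    "KineticParams",
    "LesionSpec",
    "CohortSpec",
    "PatientImaging",
    "Cohort",
    "simulate_dynamics",
    "generate_cohort",
    "write_cohort",
    "CLINICAL_COLUMNS",
    "HAZARD_FEATURE_NAMES",
]

#: exact clinical CSV header, in order
CLINICAL_COLUMNS = [
    "patient_id", "age", "psa", "ldh", "alp",
    "pfs_months", "pfs_event", "os_months", "os_event",
]

#: ground-truth feature names usable in CohortSpec.hazard_coefficients
HAZARD_FEATURE_NAMES = (
    "kpl_median", "kpl_max", "tmv", "elongation", "psa", "ldh", "alp", "age",
)

SITE_LABELS = ("bone", "liver", "node", "soft_tissue", "prostate")
# approximate per-lesion site frequencies in metastatic prostate cancer
_SITE_PROBS = (0.72, 0.10, 0.11, 0.02, 0.05)

#: administrative follow-up cap for the synthetic study, months
FOLLOW_UP_MONTHS = 36.0
#: OS baseline scale = this multiple of the PFS baseline scale
_OS_SCALE_MULTIPLIER = 2.5


@dataclass(frozen=True)
class AcquisitionConfig:
    """Dynamic ^13C acquisition parameters.

    ``noise_sigma`` is the scale of additive Gaussian magnitude noise on
    the signals, in the same arbitrary units as the signal itself.
    """

    tr_seconds: float = 3.0
    n_frames: int = 20
    flip_pyr_degrees: float = 15.0
    flip_lac_degrees: float = 30.0
    voxel_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")
        for name in ("flip_pyr_degrees", "flip_lac_degrees"):
            v = getattr(self, name)
            if not 0 < v <= 90:
                raise ValueError(f"{name} must lie in (0, 90]")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm entries must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds


@dataclass(frozen=True)
class KineticParams:
    """Voxel/lesion kinetics for the forward two-site exchange model.

    The bolus input is gamma-variate, u(t) = A * t^alpha * exp(-t/beta)
    up to normalization: ``bolus_amplitude`` is the *total* integrated
    magnetization delivered over all time, so signal amplitudes are on a
    "fraction of delivered polarization" scale.
    """

    kpl_per_second: float = 0.017
    r1p_per_second: float = 1.0 / 25.0
    r1l_per_second: float = 1.0 / 25.0
    bolus_amplitude: float = 1.0
    bolus_alpha: float = 2.5
    bolus_beta: float = 4.0

    def __post_init__(self) -> None:
        if self.kpl_per_second < 0 or self.r1p_per_second < 0 or self.r1l_per_second < 0:
            raise ValueError("rates must be nonnegative")
        if min(self.bolus_amplitude, self.bolus_alpha, self.bolus_beta) <= 0:
            raise ValueError("bolus parameters must be positive")


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    site_label: str
    kinetic: KineticParams

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii_mm must be positive")
        if self.site_label not in SITE_LABELS:
            raise ValueError(f"unknown site_label {self.site_label!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    ``hazard_coefficients`` maps ground-truth feature names (see
    :data:`HAZARD_FEATURE_NAMES`) to log-hazard weights; each feature is
    z-scored across the cohort before entering the linear predictor.
    """

    n_patients: int = 16
    lesions_per_patient: tuple[int, int] = (2, 8)
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: {"kpl_median": 1.0}
    )
    baseline_weibull_shape: float = 1.2
    baseline_weibull_scale: float = 12.0
    censor_rate: float = 0.25
    n_missing_alp: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("lesions_per_patient must be an increasing range >= 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_weibull_shape <= 0 or self.baseline_weibull_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        unknown = set(self.hazard_coefficients) - set(HAZARD_FEATURE_NAMES)
        if unknown:
            raise ValueError(
                f"unknown hazard feature name(s): {sorted(unknown)}; "
                f"valid names: {list(HAZARD_FEATURE_NAMES)}"
            )
        if not 0 <= self.n_missing_alp <= self.n_patients:
            raise ValueError("n_missing_alp out of range")


@dataclass
class PatientImaging:
    """In-memory imaging bundle for one synthetic patient."""

    patient_id: str
    pyr: np.ndarray            # (x, y, z, frame) pyruvate signal
    lac: np.ndarray            # (x, y, z, frame) lactate signal
    mask: np.ndarray           # (x, y, z) integer lesion labels, 0 = background
    affine: np.ndarray         # 4x4 voxel-to-world (mm)
    acq: AcquisitionConfig
    truth: dict                # generator-side ground-truth features
    lesions: list[LesionSpec] = field(default_factory=list)


@dataclass
class Cohort:
    patients: list[PatientImaging]
    clinical: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# forward dynamics


def _bolus_frame_integrals(params: KineticParams, acq: AcquisitionConfig) -> np.ndarray:
    """Integral of the gamma-variate input over each frame interval.

    Returns U_i = integral of u(t) over [t_i, t_{i+1}], i = 0..n_frames-2,
    normalized so that the all-time integral equals ``bolus_amplitude``.
    """
    edges = np.arange(acq.n_frames) * acq.tr_seconds
    cdf = gammainc(params.bolus_alpha + 1.0, edges / params.bolus_beta)
    return params.bolus_amplitude * np.diff(cdf)


def _propagate(
    kpl: np.ndarray,
    bolus: np.ndarray,
    acq: AcquisitionConfig,
    r1p: float,
    r1l: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared discrete recursion, vectorized over leading voxel axis.

    ``kpl`` has shape (n,), ``bolus`` shape (n, n_frames-1). Returns
    pre-pulse magnetizations P, L of shape (n, n_frames).
    """
    tr = acq.tr_seconds
    cos_p = np.cos(np.deg2rad(acq.flip_pyr_degrees))
    cos_l = np.cos(np.deg2rad(acq.flip_lac_degrees))
    ep = np.exp(-tr * r1p)
    el = np.exp(-tr * r1l)
    n = kpl.shape[0]
    P = np.zeros((n, acq.n_frames))
    L = np.zeros((n, acq.n_frames))
    for i in range(acq.n_frames - 1):
        p_post = P[:, i] * cos_p
        P[:, i + 1] = p_post * ep + bolus[:, i]
        L[:, i + 1] = L[:, i] * cos_l * el + kpl * tr * (p_post + P[:, i + 1]) / 2.0
    return P, L


def simulate_dynamics(
    params: KineticParams,
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    substeps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one voxel's dynamic pyruvate and lactate signals.

    With ``substeps=1`` (default) the signal follows the same discrete
    frame recursion that the inputless fitter inverts, so noiseless
    parameter recovery is exact. ``substeps > 1`` integrates the
    continuous-time exchange ODE (including the k_PL loss term on
    pyruvate) on a finer grid between RF pulses, to probe discretization
    bias of the frame-level model.

    Returns ``(s_pyr, s_lac)``, each of length ``acq.n_frames``:
    S_X(i) = M_X(t_i) * sin(flip_X) plus Gaussian noise of scale
    ``acq.noise_sigma`` (when a ``rng`` is given and the scale is > 0).
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    sin_p = np.sin(np.deg2rad(acq.flip_pyr_degrees))
    sin_l = np.sin(np.deg2rad(acq.flip_lac_degrees))
    if substeps == 1:
        bolus = _bolus_frame_integrals(params, acq)[None, :]
        P, L = _propagate(
            np.array([params.kpl_per_second]), bolus, acq,
            params.r1p_per_second, params.r1l_per_second,
        )
        P, L = P[0], L[0]
    else:
        P, L = _simulate_fine(params, acq, substeps)
    s_p = P * sin_p
    s_l = L * sin_l
    if acq.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        s_p = s_p + rng.normal(0.0, acq.noise_sigma, s_p.shape)
        s_l = s_l + rng.normal(0.0, acq.noise_sigma, s_l.shape)
    return s_p, s_l


def _simulate_fine(
    params: KineticParams, acq: AcquisitionConfig, substeps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time two-site exchange integrated with fine Euler steps."""
    dt = acq.tr_seconds / substeps
    cos_p = np.cos(np.deg2rad(acq.flip_pyr_degrees))
    cos_l = np.cos(np.deg2rad(acq.flip_lac_degrees))
    kpl = params.kpl_per_second
    p = l = 0.0
    P = np.zeros(acq.n_frames)
    L = np.zeros(acq.n_frames)
    for i in range(acq.n_frames - 1):
        p *= cos_p
        l *= cos_l
        t = i * acq.tr_seconds
        for k in range(substeps):
            tk = t + k * dt
            u = (
                params.bolus_amplitude
                / (params.bolus_beta ** (params.bolus_alpha + 1.0))
                / _gamma(params.bolus_alpha + 1.0)
                * tk ** params.bolus_alpha
                * np.exp(-tk / params.bolus_beta)
            )
            dp = -(params.r1p_per_second + kpl) * p + u
            dl = -params.r1l_per_second * l + kpl * p
            p += dt * dp
            l += dt * dl
        P[i + 1] = p
        L[i + 1] = l
    return P, L


def _gamma(x: float) -> float:
    from scipy.special import gamma as _g

    return float(_g(x))


# ---------------------------------------------------------------------------
# cohort generation

#: native EPI-like grid (2 cm isotropic voxels, abdominopelvic field of view)
DEFAULT_GRID_SHAPE = (16, 16, 11)


def _default_affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def _sample_lesions(
    rng: np.random.Generator,
    n_lesions: int,
    fov_mm: np.ndarray,
    patient_base_kpl: float,
) -> list[LesionSpec]:
    lesions = []
    for _ in range(n_lesions):
        radii = tuple(rng.uniform(8.0, 25.0, 3))
        margin = np.array(radii) + 5.0
        center = tuple(rng.uniform(margin, fov_mm - margin))
        site = SITE_LABELS[rng.choice(len(SITE_LABELS), p=_SITE_PROBS)]
        kpl = patient_base_kpl * rng.lognormal(0.0, 0.25)
        kin = KineticParams(
            kpl_per_second=kpl,
            bolus_amplitude=rng.lognormal(0.0, 0.3),
            bolus_beta=4.0 * rng.lognormal(0.0, 0.2),
        )
        lesions.append(LesionSpec(center, radii, site, kin))
    return lesions


def _rasterize(
    lesions: list[LesionSpec],
    shape: tuple[int, int, int],
    affine: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelize lesions onto the native grid.

    Returns (label mask, per-voxel true kpl [s^-1], per-voxel bolus
    amplitude, per-voxel bolus beta). Later lesions overwrite earlier
    ones where they overlap. Voxel-level lognormal jitter on kpl,
    amplitude and bolus timing provides intra-lesion heterogeneity for
    texture analysis (timing jitter is what gives the mean-time map its
    spatial structure).
    """
    idx = np.indices(shape).reshape(3, -1).T
    centers_mm = idx @ affine[:3, :3].T + affine[:3, 3]
    mask = np.zeros(shape, dtype=np.int16).reshape(-1)
    kpl = np.zeros(mask.shape)
    amp = np.zeros(mask.shape)
    beta = np.zeros(mask.shape)
    for k, les in enumerate(lesions, start=1):
        d = (centers_mm - np.asarray(les.center_mm)) / np.asarray(les.radii_mm)
        inside = (d ** 2).sum(axis=1) <= 1.0
        n_in = int(inside.sum())
        if n_in == 0:  # lesion smaller than a native voxel: claim nearest voxel
            inside = np.zeros(mask.shape, bool)
            inside[np.argmin((d ** 2).sum(axis=1))] = True
            n_in = 1
        mask[inside] = k
        kpl[inside] = les.kinetic.kpl_per_second * rng.lognormal(0.0, 0.2, n_in)
        amp[inside] = les.kinetic.bolus_amplitude * rng.lognormal(0.0, 0.15, n_in)
        beta[inside] = les.kinetic.bolus_beta * rng.lognormal(0.0, 0.1, n_in)
    return (mask.reshape(shape), kpl.reshape(shape),
            amp.reshape(shape), beta.reshape(shape))


def _truth_features(
    mask: np.ndarray, kpl_s: np.ndarray, affine: np.ndarray
) -> dict[str, float]:
    inmask = mask > 0
    vox_ml = float(abs(np.linalg.det(affine[:3, :3]))) / 1000.0
    kpl_ks = kpl_s[inmask] * 1000.0
    coords = np.argwhere(inmask) @ affine[:3, :3].T + affine[:3, 3]
    if coords.shape[0] >= 2:
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        elong = float(np.sqrt(max(lam[1], 0.0) / lam[0])) if lam[0] > 0 else 1.0
    else:
        elong = 1.0
    return {
        "kpl_median": float(np.median(kpl_ks)),
        "kpl_max": float(kpl_ks.max()),
        "tmv": float(inmask.sum() * vox_ml),
        "elongation": elong,
    }


def _draw_survival(
    rng: np.random.Generator,
    eta: np.ndarray,
    spec: CohortSpec,
) -> pd.DataFrame:
    """Weibull-baseline proportional-hazards times with right censoring.

    T = scale * (-log(U) / exp(eta))^(1/shape) by inverse-transform
    sampling. One common censoring time per patient: the follow-up cap,
    or (with probability ``censor_rate``) an early dropout uniform over
    the follow-up window. OS is drawn from the same linear predictor
    with a longer baseline scale and floored at the PFS time.
    """
    n = eta.shape[0]
    shape = spec.baseline_weibull_shape
    u1 = rng.uniform(size=n)
    u2 = rng.uniform(size=n)
    t_pfs = spec.baseline_weibull_scale * (-np.log(u1) / np.exp(eta)) ** (1.0 / shape)
    t_os = (
        spec.baseline_weibull_scale * _OS_SCALE_MULTIPLIER
        * (-np.log(u2) / np.exp(eta)) ** (1.0 / shape)
    )
    t_os = np.maximum(t_os, t_pfs)
    cens = np.full(n, FOLLOW_UP_MONTHS)
    dropout = rng.uniform(size=n) < spec.censor_rate
    cens[dropout] = rng.uniform(1.0, FOLLOW_UP_MONTHS, size=n)[dropout]
    pfs_event = (t_pfs <= cens).astype(int)
    os_event = (t_os <= cens).astype(int)
    return pd.DataFrame(
        {
            "pfs_months": np.round(np.minimum(t_pfs, cens), 3),
            "pfs_event": pfs_event,
            "os_months": np.round(np.minimum(t_os, cens), 3),
            "os_event": os_event,
        }
    )


#: default cohort noise scale: peak pyruvate signal of the default
#: kinetics is ~0.148 (fraction-of-delivered-polarization units), so this
#: puts peak SNR near 20.
DEFAULT_NOISE_SIGMA = 0.0074


def generate_cohort(
    spec: CohortSpec,
    acq: AcquisitionConfig | None = None,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
) -> Cohort:
    """Generate a full synthetic cohort.

    Identical ``spec`` (including seed) and ``acq`` yield an identical
    cohort, bit for bit.
    """
    if acq is None:
        acq = AcquisitionConfig(noise_sigma=DEFAULT_NOISE_SIGMA)
    rng = np.random.default_rng(spec.seed)
    affine = _default_affine(acq.voxel_mm)
    fov_mm = np.array(grid_shape) * np.array(acq.voxel_mm)
    sin_p = np.sin(np.deg2rad(acq.flip_pyr_degrees))
    sin_l = np.sin(np.deg2rad(acq.flip_lac_degrees))

    patients: list[PatientImaging] = []
    rows = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        n_lesions = int(rng.integers(spec.lesions_per_patient[0],
                                     spec.lesions_per_patient[1] + 1))
        # patient-level base kpl, lognormal around ~15 ks^-1
        base_kpl = rng.lognormal(np.log(0.015), 0.45)
        lesions = _sample_lesions(rng, n_lesions, fov_mm, base_kpl)
        mask, kpl_vox, amp_vox, beta_vox = _rasterize(lesions, grid_shape, affine, rng)

        inmask = mask.reshape(-1) > 0
        kin0 = lesions[0].kinetic
        # per-voxel bolus integrals (per-voxel timing beta, common alpha)
        edges = np.arange(acq.n_frames) * acq.tr_seconds
        cdf = gammainc(
            kin0.bolus_alpha + 1.0,
            edges[None, :] / beta_vox.reshape(-1)[inmask][:, None],
        )
        bolus = amp_vox.reshape(-1)[inmask][:, None] * np.diff(cdf, axis=1)
        P, L = _propagate(
            kpl_vox.reshape(-1)[inmask], bolus, acq,
            kin0.r1p_per_second, kin0.r1l_per_second,
        )
        nvox = int(np.prod(grid_shape))
        s_p = np.zeros((nvox, acq.n_frames))
        s_l = np.zeros((nvox, acq.n_frames))
        s_p[inmask] = P * sin_p
        s_l[inmask] = L * sin_l
        if acq.noise_sigma > 0:
            s_p += rng.normal(0.0, acq.noise_sigma, s_p.shape)
            s_l += rng.normal(0.0, acq.noise_sigma, s_l.shape)
        shape4 = grid_shape + (acq.n_frames,)

        truth = _truth_features(mask, kpl_vox, affine)
        truth["age"] = float(np.clip(rng.normal(69.0, 10.0), 52.0, 88.0))
        patients.append(
            PatientImaging(
                patient_id=pid,
                pyr=s_p.reshape(shape4),
                lac=s_l.reshape(shape4),
                mask=mask,
                affine=affine,
                acq=acq,
                truth=truth,
                lesions=lesions,
            )
        )

    # serology: PSA moderately coupled to metabolic tumor volume
    tmv = np.array([pt.truth["tmv"] for pt in patients])
    z_tmv = _zscore(tmv)
    for pt, z in zip(patients, z_tmv):
        pt.truth["psa"] = float(np.exp(np.log(13.9) + 0.7 * z + rng.normal(0.0, 0.9)))
        pt.truth["ldh"] = float(rng.lognormal(np.log(208.0), 0.35))
        pt.truth["alp"] = float(rng.lognormal(np.log(76.0), 0.45))

    # linear predictor from z-scored ground-truth features
    eta = np.zeros(spec.n_patients)
    for name, w in spec.hazard_coefficients.items():
        vals = np.array([pt.truth[name] for pt in patients])
        eta += w * _zscore(vals)
    surv = _draw_survival(rng, eta, spec)

    missing_idx = (
        rng.choice(spec.n_patients, size=spec.n_missing_alp, replace=False)
        if spec.n_missing_alp
        else np.array([], dtype=int)
    )
    for i, pt in enumerate(patients):
        rows.append(
            {
                "patient_id": pt.patient_id,
                "age": round(pt.truth["age"], 1),
                "psa": round(pt.truth["psa"], 2),
                "ldh": round(pt.truth["ldh"], 1),
                "alp": np.nan if i in missing_idx else round(pt.truth["alp"], 1),
                **surv.iloc[i].to_dict(),
            }
        )
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    clinical["pfs_event"] = clinical["pfs_event"].astype(int)
    clinical["os_event"] = clinical["os_event"].astype(int)

    manifest = {
        "seed": spec.seed,
        "spec": _spec_to_dict(spec),
        "acquisition": dataclasses.asdict(acq),
        "grid_shape": list(grid_shape),
        "n_patients": spec.n_patients,
    }
    return Cohort(patients=patients, clinical=clinical, manifest=manifest)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["lesions_per_patient"] = list(d["lesions_per_patient"])
    return d


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write per-patient NIfTIs, the clinical CSV, and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for pt in cohort.patients:
        for name, arr in (("pyr", pt.pyr), ("lac", pt.lac)):
            img = nib.Nifti1Image(arr.astype(np.float32), pt.affine)
            img.header.set_zooms(pt.acq.voxel_mm + (pt.acq.tr_seconds,))
            p = out / f"{pt.patient_id}_{name}.nii.gz"
            nib.save(img, p)
            paths[f"{pt.patient_id}_{name}"] = p
        m = nib.Nifti1Image(pt.mask.astype(np.int16), pt.affine)
        p = out / f"{pt.patient_id}_mask.nii.gz"
        nib.save(m, p)
        paths[f"{pt.patient_id}_mask"] = p
    clin_path = out / "clinical.csv"
    cohort.clinical.to_csv(clin_path, index=False, float_format="%.6g")
    paths["clinical"] = clin_path
    man_path = out / "cohort_manifest.json"
    man_path.write_text(json.dumps(cohort.manifest, indent=2, sort_keys=True))
    paths["manifest"] = man_path
    return paths
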