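"""End-to-end pipeline: simulate -> maps -> features -> survival -> MPS.

Configuration is a strict dataclass tree that round-trips through
YAML/JSON; unknown keys are rejected by name. Every stage writes
standard formats (NIfTI volumes, CSV tables, JSON reports) into the run
directory, a manifest captures the config hash, seed and per-stage
counts, and a rerun with an identical config reproduces byte-identical
tables. Completed stages can be resumed from their cached outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    AcquisitionConfig,
    Cohort,
    CohortSpec,
    DEFAULT_NOISE_SIGMA,
    PatientImaging,
    generate_cohort,
    write_cohort,
)
from .features import DiscretizationConfig, cohort_feature_matrix
from .kinetics import (
    DynamicSeries,
    KineticModelConfig,
    ParametricMapSet,
    compute_maps,
    load_map_set,
    resample_maps,
    save_map_set,
)
from .selection import (
    SelectionConfig,
    build_mps,
    cluster_and_select,
    loo_stability,
    rank_and_retain,
    correlogram,
)
from .survival import cox_fit, impute_alp, km_by_group

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "univariate_report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "maps", "features", "survival", "select")

#: Table-style default rows for the univariate report
DEFAULT_UNIVARIATE_FEATURES = (
    "kPL_original_firstorder_Maximum",
    "kPL_original_firstorder_Median",
    "kPL_original_firstorder_Kurtosis",
    "TMV",
    "psa",
    "ldh",
    "alp",
)


def _strict_dataclass(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return data


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "hpmfm_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    kpl_cutoff: float | None = None   # None: dichotomize at the cohort median
    univariate_features: tuple[str, ...] = DEFAULT_UNIVARIATE_FEATURES
    resample_voxel_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(noise_sigma=DEFAULT_NOISE_SIGMA)
    )
    kinetic_model: KineticModelConfig = field(default_factory=KineticModelConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["univariate_features"] = list(self.univariate_features)
        d["resample_voxel_mm"] = list(self.resample_voxel_mm)
        d["cohort"]["lesions_per_patient"] = list(self.cohort.lesions_per_patient)
        d["acquisition"]["voxel_mm"] = list(self.acquisition.voxel_mm)
        d["kinetic_model"]["kpl_bounds_per_second"] = list(
            self.kinetic_model.kpl_bounds_per_second
        )
        d["selection"]["serology_features"] = list(self.selection.serology_features)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(_strict_dataclass(cls, data, "config"))
        sub = {
            "cohort": (CohortSpec, {"lesions_per_patient": tuple}),
            "acquisition": (AcquisitionConfig, {"voxel_mm": tuple}),
            "kinetic_model": (KineticModelConfig, {"kpl_bounds_per_second": tuple}),
            "discretization": (DiscretizationConfig, {}),
            "selection": (SelectionConfig, {"serology_features": tuple}),
        }
        for key, (subcls, casts) in sub.items():
            if key in data and isinstance(data[key], dict):
                payload = dict(_strict_dataclass(subcls, data[key], f"config.{key}"))
                for name, cast in casts.items():
                    if name in payload:
                        payload[name] = cast(payload[name])
                data[key] = subcls(**payload)
        for name in ("stages", "univariate_features", "resample_voxel_mm"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    clinical: pd.DataFrame
    features: pd.DataFrame | None
    univariate: pd.DataFrame | None
    mps_report: dict | None
    paths: dict[str, Path]


def univariate_report(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    feature_names: tuple[str, ...] | list[str] = DEFAULT_UNIVARIATE_FEATURES,
) -> pd.DataFrame:
    """Per-feature univariate Cox LRT p and C-index for PFS and OS.

    Serology names are looked up in the clinical table (ALP imputed);
    constant columns are reported with NaN entries.
    """
    clin = impute_alp(clinical).set_index("patient_id").loc[feature_matrix.index]
    rows = []
    for name in feature_names:
        if name in feature_matrix.columns:
            col = feature_matrix[name].to_numpy(dtype=float)
        elif name in clin.columns:
            col = clin[name].to_numpy(dtype=float)
        else:
            logger.warning("univariate_report: feature %r not found; skipped", name)
            continue
        row: dict[str, object] = {"feature": name}
        for ep in ("pfs", "os"):
            t = clin[f"{ep}_months"].to_numpy(float)
            e = clin[f"{ep}_event"].to_numpy(int)
            try:
                fit = cox_fit(pd.DataFrame({name: col}), t, e)
                hr = fit.hazard_ratios.iloc[0]
                row[f"{ep}_p"] = fit.lrt_p
                row[f"{ep}_c_index"] = fit.c_index
                row[f"{ep}_hr"] = hr["HR"]
                row[f"{ep}_hr_lower95"] = hr["lower95"]
                row[f"{ep}_hr_upper95"] = hr["upper95"]
            except ValueError:
                for k in ("p", "c_index", "hr", "hr_lower95", "hr_upper95"):
                    row[f"{ep}_{k}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _km_table(groups: dict) -> pd.DataFrame:
    frames = []
    for name, curve in groups.items():
        if curve is None:
            continue
        f = curve.as_frame()
        f.insert(0, "group", name)
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "time", "survival", "at_risk"]
    )


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def _load_cohort_images(cohort_dir: Path, clinical: pd.DataFrame,
                        acq: AcquisitionConfig) -> list[PatientImaging]:
    patients = []
    for pid in clinical["patient_id"]:
        pyr = nib.load(cohort_dir / f"{pid}_pyr.nii.gz")
        lac = nib.load(cohort_dir / f"{pid}_lac.nii.gz")
        mask = nib.load(cohort_dir / f"{pid}_mask.nii.gz")
        patients.append(
            PatientImaging(
                patient_id=pid,
                pyr=np.asarray(pyr.dataobj, float),
                lac=np.asarray(lac.dataobj, float),
                mask=np.asarray(mask.dataobj).astype(np.int16),
                affine=pyr.affine,
                acq=acq,
                truth={},
            )
        )
    return patients


def run_pipeline(config: PipelineConfig, resume: bool = False) -> PipelineResult:
    """Execute the configured stage prefix and write all artifacts.

    With ``resume=True`` a stage whose outputs already exist in the run
    directory is loaded instead of recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    stages = config.stages

    # --- simulate ---------------------------------------------------------
    cohort_dir = out / "cohort"
    clin_path = cohort_dir / "clinical.csv"
    cohort: Cohort | None = None
    if "simulate" in stages:
        if resume and clin_path.exists():
            logger.info("simulate: resuming from %s", cohort_dir)
            clinical = pd.read_csv(clin_path)
            patients = _load_cohort_images(cohort_dir, clinical, config.acquisition)
        else:
            cohort = generate_cohort(spec, config.acquisition)
            write_cohort(cohort, cohort_dir)
            clinical, patients = cohort.clinical, cohort.patients
        paths["clinical"] = clin_path
        manifest["stages"]["simulate"] = {
            "n_patients": int(len(patients)),
            "n_lesions": int(sum(int(p.mask.max()) for p in patients)),
        }
    else:
        if not clin_path.exists():
            raise FileNotFoundError(
                f"stage 'simulate' disabled but no cached cohort at {cohort_dir}"
            )
        clinical = pd.read_csv(clin_path)
        patients = _load_cohort_images(cohort_dir, clinical, config.acquisition)

    # --- maps -------------------------------------------------------------
    maps_dir = out / "maps"
    patient_maps: dict[str, ParametricMapSet] = {}
    if "maps" in stages:
        maps_dir.mkdir(exist_ok=True)
        fit_stats: dict[str, dict] = {}
        for pt in patients:
            done = maps_dir / f"{pt.patient_id}_kpl.nii.gz"
            if resume and done.exists():
                patient_maps[pt.patient_id] = load_map_set(maps_dir, pt.patient_id)
                continue
            native = compute_maps(
                DynamicSeries.from_patient(pt), pt.mask, config.kinetic_model
            )
            iso = resample_maps(native, config.resample_voxel_mm)
            patient_maps[pt.patient_id] = iso
            save_map_set(iso, maps_dir, pt.patient_id)
            inmask = native.mask > 0
            fit_stats[pt.patient_id] = {
                "n_positive_kpl_voxels_native": int((native.kpl_map > 0).sum()),
                "n_mask_voxels_native": int(inmask.sum()),
                "kpl_median_inmask_ks": float(np.median(native.kpl_map[inmask]))
                if inmask.any() else 0.0,
                "kpl_max_inmask_ks": float(native.kpl_map[inmask].max())
                if inmask.any() else 0.0,
            }
        if fit_stats:
            (maps_dir / "fit_stats.json").write_text(
                json.dumps(fit_stats, indent=2, sort_keys=True)
            )
        manifest["stages"]["maps"] = {
            "n_patients": len(patient_maps),
            "n_positive_kpl_voxels_native": sum(
                s["n_positive_kpl_voxels_native"] for s in fit_stats.values()
            ),
        }

    # --- features ---------------------------------------------------------
    feat_path = out / "features.csv"
    features: pd.DataFrame | None = None
    if "features" in stages:
        if resume and feat_path.exists():
            features = pd.read_csv(feat_path, index_col="patient_id").astype(float)
        else:
            if not patient_maps:
                for pid in clinical["patient_id"]:
                    patient_maps[pid] = load_map_set(maps_dir, pid)
            features = cohort_feature_matrix(patient_maps, config.discretization)
            _write_csv(features, feat_path)
        paths["features"] = feat_path
        manifest["stages"]["features"] = {
            "n_patients": int(features.shape[0]),
            "n_features": int(features.shape[1]),
        }
    elif feat_path.exists():
        features = pd.read_csv(feat_path, index_col="patient_id").astype(float)

    univariate = None
    mps_report = None
    clinical_used = clinical[clinical["patient_id"].isin(
        features.index if features is not None else clinical["patient_id"]
    )]

    # --- survival (univariate table + dichotomized KM) --------------------
    if "survival" in stages:
        if features is None:
            raise FileNotFoundError("stage 'survival' needs the feature matrix")
        univariate = univariate_report(
            features, clinical_used, config.univariate_features
        )
        uni_path = out / "univariate.csv"
        _write_csv(univariate, uni_path, index=False)
        paths["univariate"] = uni_path

        med_col = "kPL_original_firstorder_Median"
        cutoff = (
            float(features[med_col].median())
            if config.kpl_cutoff is None
            else float(config.kpl_cutoff)
        )
        km_rows = []
        for ep in ("pfs", "os"):
            groups = km_by_group(
                features[med_col].to_numpy(float),
                cutoff,
                clinical_used[f"{ep}_months"].to_numpy(float),
                clinical_used[f"{ep}_event"].to_numpy(int),
            )
            tab = _km_table(groups)
            tab.insert(0, "endpoint", ep)
            km_rows.append(tab)
        km_path = out / "km_kpl_median.csv"
        _write_csv(pd.concat(km_rows, ignore_index=True), km_path, index=False)
        paths["km_kpl_median"] = km_path
        manifest["stages"]["survival"] = {
            "kpl_median_cutoff": cutoff,
            "n_rows": int(univariate.shape[0]),
        }

    # --- select (ranking, clustering, MPS, LOO) ---------------------------
    if "select" in stages:
        if features is None:
            raise FileNotFoundError("stage 'select' needs the feature matrix")
        ranking = rank_and_retain(features, clinical_used, config.selection)
        clusters = cluster_and_select(
            ranking.matrix[ranking.retained], ranking.scores, config.selection
        )
        model = build_mps(
            features, clinical_used, clusters.representatives, config.selection
        )
        loo = loo_stability(
            features, clinical_used, clusters.representatives, config.selection
        )
        corr = correlogram(
            features, clinical_used, clusters.representatives, config.selection
        )

        selection_report = {
            "scores": {k: float(v) for k, v in ranking.scores.items()},
            "retained": ranking.retained,
            "clusters": clusters.assignments,
            "representatives": clusters.representatives,
        }
        sel_path = out / "selection.json"
        sel_path.write_text(json.dumps(selection_report, indent=2, sort_keys=True))
        mps_report = {
            "selected_features": model.selected_features,
            "coefficients": {k: float(v) for k, v in model.coefficients.items()},
            "threshold": model.threshold,
            "lrt_p": model.lrt_p,
            "c_index": model.c_index,
            "km_median": {
                ep: {
                    g: (c.median_label if c is not None else None)
                    for g, c in km.items()
                }
                for ep, km in (("pfs", model.km_pfs), ("os", model.km_os))
            },
            "loo_normalized_sd": loo.normalized_sd,
            "loo_n_refits": loo.n_refits,
            "loo_n_failures": loo.n_failures,
            "ridge_stabilized": model.ridge_stabilized,
        }
        mps_path = out / "mps_model.json"
        mps_path.write_text(json.dumps(mps_report, indent=2, sort_keys=True))
        corr_path = out / "correlogram.csv"
        _write_csv(corr, corr_path)
        km_mps = []
        for ep, km in (("pfs", model.km_pfs), ("os", model.km_os)):
            tab = _km_table(km)
            tab.insert(0, "endpoint", ep)
            km_mps.append(tab)
        km_mps_path = out / "km_mps.csv"
        _write_csv(pd.concat(km_mps, ignore_index=True), km_mps_path, index=False)
        paths.update(
            selection=sel_path, mps_model=mps_path,
            correlogram=corr_path, km_mps=km_mps_path,
        )
        manifest["stages"]["select"] = {
            "n_scored": len(ranking.scores),
            "n_retained": len(ranking.retained),
            "representatives": clusters.representatives,
        }

    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = man_path
    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        clinical=clinical,
        features=features,
        univariate=univariate,
        mps_report=mps_report,
        paths=paths,
    )
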