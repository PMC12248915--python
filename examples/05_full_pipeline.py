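"""Run the whole pipeline (simulate -> maps -> features -> survival ->
select) from one configuration object and inspect the artifacts.

Every stage writes standard formats into the run directory: NIfTI
volumes, the clinical CSV, the feature matrix CSV, the univariate Cox
table, Kaplan-Meier step tables, the selection/MPS JSON reports, and a
manifest with the config hash. Rerunning the same config reproduces the
tables byte for byte.
"""

import json
import tempfile
from pathlib import Path

from hpmfm import CohortSpec, PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        out_dir=str(Path(tmp) / "demo_run"),
        seed=1,
        cohort=CohortSpec(n_patients=16),  # the study-sized default
    )
    result = run_pipeline(cfg)

    print("artifacts written:")
    for key, path in sorted(result.paths.items()):
        print(f"  {key:15s} {path.name}")

    uni = result.univariate.set_index("feature")
    print("\nunivariate Cox table (LRT p-values):")
    print(uni[["pfs_p", "pfs_c_index", "os_p", "os_c_index"]].round(3).to_string())

    rep = result.mps_report
    print("\nMPS model:")
    print("  representatives:", rep["selected_features"])
    print("  coefficients:   ", json.dumps(
        {k: round(v, 4) for k, v in rep["coefficients"].items()}))
    print(f"  threshold (median MPS): {rep['threshold']:.4f}")
    print(f"  C-index: {rep['c_index']}")
    print(f"  LOO normalized SDs: "
          f"{ {k: round(float(v), 3) for k, v in rep['loo_normalized_sd'].items()} }")
# At n = 16 the coefficient stability is limited (normalized SDs well
# above zero) - exactly the small-sample caveat the leave-one-out
# analysis is there to expose.
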