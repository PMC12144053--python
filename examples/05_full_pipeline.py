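"""One-call pipeline run producing the complete artifact bundle.

Equivalent to ``sm-phenotype report --out scratch/example_run --seed 11``:
yield report, hourly/daily feature tables, per-app descriptives, stats
report JSON, figures, and a manifest sufficient to reproduce the bundle.
"""

import json

from sm_phenotype.pipeline import PipelineConfig, run_pipeline
from sm_phenotype.synthetic import CohortConfig

config = PipelineConfig(
    output_dir="scratch/example_run",
    cohort=CohortConfig(n_participants=6, n_days=14, seed=11),
    seed=11,
)
result = run_pipeline(config)

print("artifacts written:")
for name, path in sorted(result.paths.items()):
    print(f"  {name:<32} {path}")

report = json.loads(result.paths["stats_report"].read_text())
broad = report["categories"]["broad"]
print()
print(f"study yield ratio: {report['data_yield']['study_pooled']:.3f}")
print(f"broad daily duration, between-person mean: "
      f"{broad['between_person_duration']['mean']:.1f} min")
print(f"broad duration ICC between-fraction: "
      f"{broad['icc_duration']['between_fraction']:.2f}")
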