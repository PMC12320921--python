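"""Config-driven end-to-end run: simulate -> metrics -> PLS -> QC -> report.

Equivalent YAML (loadable with RunConfig.from_yaml) is shown alongside the
programmatic config.  Outputs land in ./scratch/pipeline_demo as CSVs plus a
manifest recording the package version, config hash and all seeds.
"""

from devconn import RunConfig, run_pipeline, write_report
from devconn.pipeline import PLSAnalysisConfig

config = RunConfig(
    output_dir="scratch/pipeline_demo",
    simulate={"n_subjects": 15, "n_regions": 60},
    metrics=["fc_degree", "fc_clustering"],
    pls=[
        PLSAnalysisConfig("mean_centered", "fc_degree"),
        PLSAnalysisConfig("behavioral", "fc_degree",
                          ["age", "sustained", "selective", "executive"]),
    ],
    n_perm=200,
    n_boot=100,
    n_splits=100,
    n_perm_reproducibility=10,
    run_reproducibility=True,
    fingerprint=True,
    n_nulls=50,
    seed=11,
)

results = run_pipeline(config)
print(write_report(results))
print("Files written:", ", ".join(results["manifest"]["outputs"]))
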