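"""The whole pipeline in one call: simulate, split, augment, classify, report.

Runs the default desk-scale profile (1% layer widths, 300 epochs per
stage) on the planted 16-region cohort and prints the held-out metric
table. Artifacts (feature table, split plan, model bundles, predictions,
report, manifest) land in the run directory.
"""

from fcgan import FixtureConfig, RunConfig, run_pipeline
from fcgan.evaluation import format_table

config = RunConfig(
    out_dir="scratch/example_run",
    fixture=FixtureConfig(seed=7),  # 4 sites, 200 ASD + 200 HC, planted Δr=0.4
    protocol="holdout",             # stratified by (site, class)
    ablation="full",                # cGAN augmentation + attention classifier
    n_synth_per_class=1000,
    seed=7,
)
result = run_pipeline(config)

print(format_table(result.table))
print()
pooled = result.pooled
print(f"held-out accuracy {100 * pooled['accuracy']:.1f}%, "
      f"AUC {pooled['auc']:.3f} on {pooled['n']} test subjects.")
print("accuracy near 100% means the classifier recovered the planted "
      "correlation difference; chance would be ~50%.")
print(f"artifacts and manifest: {result.out_dir}/")
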