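"""Desk-scale end-to-end run: augmentation cases 1 and 2 on synthetic data.

Runs the full leakage-safe pipeline at 10% of the study's class counts: five
stratified folds, one DCGAN per class per fold trained on that fold's
training images only (case 2), and a two-point classifier grid.  Prints the
ranked report — each row is a grid point with its five-fold mean and standard
deviation of micro/macro AUC.  On these well-separated synthetic textures
both cases should reach mean micro AUC >= 0.9.
"""

import pandas as pd

from cystaug import PipelineConfig, SyntheticDatasetConfig, run_grid

config = PipelineConfig(
    dataset=SyntheticDatasetConfig(per_class_counts=(90, 60, 68, 34), master_seed=1),
    architectures=("alexnet",),
    gan_epochs=(50,),
    cases=(1, 2),
    solvers=("Adam",),
    batch_sizes=(8,),
    classifier_epochs=(5,),
    seed=0,
    profile="desk",
    out_dir="scratch_grid_demo",
)

records, ranked, summary = run_grid(config)

print(pd.read_csv("scratch_grid_demo/ranked.csv").round(4).to_string(index=False))
print("\ngrid population summary:")
for key, value in summary.items():
    print(f"  {key}: {value:.4f}")
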