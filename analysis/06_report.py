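"""Statistical comparisons and figures for the finished experiment.

Runs the chance-level one-sample tests and the multi-vs-single Welch
comparisons over the per-seed metric tables, then renders confusion
heatmaps, metric bar charts with per-seed points, and t-SNE panels.
"""

import json
import pandas as pd

from numsense.experiment import (
    ExperimentConfig,
    _classifiers,
    make_report,
    stage_eval_arithmetic,
    stage_eval_generation,
    stage_eval_latent,
    stage_generate,
    stage_stats,
    stage_train,
)

cfg = ExperimentConfig(out_dir="results/full")
ds = stage_generate(cfg)
multi, single = stage_train(cfg, ds)
clfs = _classifiers(cfg, ds)
gen_df = stage_eval_generation(cfg, ds, multi, single, clfs)
lat_df = stage_eval_latent(cfg, ds, multi, single)
arith_df = stage_eval_arithmetic(cfg, ds, multi, single, clfs)
stats = stage_stats(cfg, gen_df, lat_df, arith_df)

print(json.dumps(stats, indent=2))
written = make_report(cfg.out_dir)
print("\nfigures written:")
for p in written:
    print(" ", p)
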