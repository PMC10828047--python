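"""Latent-space quality: silhouettes and number-line correlations.

All metrics are computed in the original 20-d latent space from posterior
means of test images; the multimodal and single-modal ensembles are
summarized side by side, including the linear-vs-log scale comparison.
"""

from numsense.experiment import ExperimentConfig, stage_eval_latent, stage_generate, stage_train

cfg = ExperimentConfig(out_dir="results/full")
ds = stage_generate(cfg)
multi, single = stage_train(cfg, ds)

df = stage_eval_latent(cfg, ds, multi, single)
summary = df.groupby(["mode", "modality"]).mean(numeric_only=True).round(3)
print(summary[["silhouette_number", "silhouette_color", "silhouette_shape",
               "centroid_corr_linear", "centroid_corr_log"]])
print("\nlinear vs log number-line fit (higher = better match):")
print(summary[["centroid_corr_linear", "centroid_corr_log"]])
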