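"""Latent arithmetic probe over the balanced expression set.

Encodes operand images, combines z_a + z_b - z_c outside the network,
decodes, and scores the result with the oracle classifier.
"""

from numsense.experiment import (
    CHANCE_LEVEL,
    ExperimentConfig,
    _classifiers,
    stage_eval_arithmetic,
    stage_generate,
    stage_train,
)

cfg = ExperimentConfig(out_dir="results/full")
ds = stage_generate(cfg)
multi, single = stage_train(cfg, ds)
clfs = _classifiers(cfg, ds)

df = stage_eval_arithmetic(cfg, ds, multi, single, clfs)
summary = df.groupby(["mode", "modality"]).mean(numeric_only=True).round(3)
print(summary)
print(f"chance level: {CHANCE_LEVEL:.3f}")
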