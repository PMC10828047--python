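"""Score reconstruction and cross-generation with the oracle classifiers.

For every trained model, test images are reconstructed (and, for the
multimodal models, cross-generated into the other modality); an independent
classifier reads the number from each output and accuracies are tallied
against chance (1/9).
"""

from numsense.experiment import (
    CHANCE_LEVEL,
    ExperimentConfig,
    _classifiers,
    stage_eval_generation,
    stage_generate,
    stage_train,
)

cfg = ExperimentConfig(out_dir="results/full")
ds = stage_generate(cfg)
multi, single = stage_train(cfg, ds)
clfs = _classifiers(cfg, ds)
print("oracle clean accuracies:", {m: round(c.clean_accuracy, 3) for m, c in clfs.items()})

df = stage_eval_generation(cfg, ds, multi, single, clfs)
summary = df.groupby(["mode", "modality"]).mean(numeric_only=True).round(3)
print(summary)
print(f"chance level: {CHANCE_LEVEL:.3f}")
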