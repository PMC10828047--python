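"""Train the multimodal and single-modal seed ensembles.

Five seeds per mode at the default scale; checkpoints land under
results/full/checkpoints and the run resumes from any that already exist.
"""

from numsense.experiment import ExperimentConfig, stage_generate, stage_train

cfg = ExperimentConfig(out_dir="results/full")
ds = stage_generate(cfg)
multi, single = stage_train(cfg, ds, verbose=True)

for ens, mode in ((multi, "multi"), (single, "single")):
    for seed, _, log in ens.members:
        if "loss" in log:
            print(f"{mode} seed {seed}: loss {log['loss'][0]:.0f} -> {log['loss'][-1]:.0f}")
        else:
            print(f"{mode} seed {seed}: resumed from checkpoint")
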