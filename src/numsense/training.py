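"""Training loops for multi- and single-mode models and seed ensembles.

A fixed-budget regime: Adam, fixed epoch count, no early stopping.  Every
source of randomness (parameter init, minibatch order, reparameterization
noise) is derived from the run seed, so a repeated run reproduces the final
parameters bit-identically on a single thread.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import PairedDataset
from .mmvae import MultimodalModel, moe_objective, single_objective
from .nn import Adam

__all__ = ["TrainConfig", "TrainedEnsemble", "train_model", "train_ensemble"]


@dataclass
class TrainConfig:
    mode: str = "multi"
    latent_dim: int = 20
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    K: int = 1
    hidden: int = 256
    likelihood_scale: float = 0.1
    likelihood: str = "gaussian"
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.mode not in ("multi", "single"):
            raise ValueError(f"mode must be 'multi' or 'single', got {self.mode!r}")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not self.seeds:
            raise ValueError("seed list must be non-empty")


@dataclass
class TrainedEnsemble:
    """One independently trained model per seed, sharing a TrainConfig."""

    config: TrainConfig
    members: list[tuple[int, MultimodalModel, dict]] = field(default_factory=list)

    @property
    def models(self) -> list[MultimodalModel]:
        return [m for _, m, _ in self.members]

    @property
    def seeds(self) -> list[int]:
        return [s for s, _, _ in self.members]


def train_model(
    config: TrainConfig,
    dataset: PairedDataset,
    seed: int,
    checkpoint: str | Path | None = None,
    verbose: bool = False,
) -> tuple[MultimodalModel, dict]:
    """Train one model on the dataset's train split.

    Returns ``(model, log)`` where the log records per-epoch mean losses
    (negated objective).  In single mode the two autoencoders' losses are
    tracked separately — they share no parameters and no latent exchange
    occurs.  A non-finite loss aborts with a diagnostic.
    """
    train = dataset.split("train")
    if len(train) == 0:
        raise ValueError("dataset has no train split")
    canvas = train.oscn.shape[1]
    model = MultimodalModel(
        mode=config.mode,
        latent_dim=config.latent_dim,
        canvas_size=canvas,
        hidden=config.hidden,
        likelihood_scale=config.likelihood_scale,
        likelihood=config.likelihood,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=config.lr)
    n = len(train)
    log: dict = {"epochs": [], "loss": [], "loss_oscn": [], "loss_cmnist": [], "seed": seed}
    t0 = time.time()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, losses_o, losses_c = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xo, xc = train.oscn[idx], train.cmnist[idx]
            opt.zero_grad()
            if config.mode == "multi":
                obj = moe_objective(model, xo, xc, K=config.K, rng=rng)
                loss = -obj
                losses.append(float(loss.data))
            else:
                obj_o = single_objective(model, xo, "oscn", K=config.K, rng=rng)
                obj_c = single_objective(model, xc, "cmnist", K=config.K, rng=rng)
                loss = -(obj_o + obj_c)
                losses.append(float(loss.data))
                losses_o.append(float(-obj_o.data))
                losses_c.append(float(-obj_c.data))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} seed {seed} "
                    f"(mode={config.mode}); lower lr or likelihood scale"
                )
            loss.backward()
            opt.step()
        log["epochs"].append(epoch)
        log["loss"].append(float(np.mean(losses)))
        if config.mode == "single":
            log["loss_oscn"].append(float(np.mean(losses_o)))
            log["loss_cmnist"].append(float(np.mean(losses_c)))
        if verbose:
            print(f"seed {seed} epoch {epoch + 1}/{config.epochs} loss {log['loss'][-1]:.1f}")
    log["wall_seconds"] = time.time() - t0
    if checkpoint is not None:
        model.save(checkpoint)
    return model, log


def train_ensemble(
    config: TrainConfig,
    dataset: PairedDataset,
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> TrainedEnsemble:
    """Train one model per seed; resumable from per-seed checkpoints.

    If ``out_dir`` is given, a member whose checkpoint already exists is
    loaded instead of retrained, so an interrupted run resumes to the same
    result.  Per-seed failures propagate with the seed identity attached.
    """
    ensemble = TrainedEnsemble(config=config)
    for seed in config.seeds:
        ckpt = None
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            ckpt = Path(out_dir) / f"{config.mode}_seed{seed}.npz"
        try:
            if ckpt is not None and ckpt.exists():
                model = MultimodalModel.load(ckpt)
                log = {"seed": seed, "resumed": True}
            else:
                model, log = train_model(config, dataset, seed, checkpoint=ckpt, verbose=verbose)
        except Exception as exc:
            raise RuntimeError(f"training failed for seed {seed} (mode={config.mode})") from exc
        ensemble.members.append((seed, model, log))
    return ensemble
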