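"""Shared fixtures: small datasets and trained models reused across tests.

Training fixtures are session-scoped because even desk-scale VAE training
costs tens of seconds; every test that needs a trained model shares the same
one rather than retraining.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from numsense import build_paired_dataset, train_classifier
from numsense.training import TrainConfig, train_model

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """900 balanced pairs (100 per number class), 32x32, glyph digits."""
    return build_paired_dataset(900, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """90 pairs — enough for structural checks, too small for training."""
    return build_paired_dataset(90, seed=3)


@pytest.fixture(scope="session")
def number_classifiers(small_dataset):
    return {
        m: train_classifier(small_dataset, m, "number", seed=0)
        for m in ("oscn", "cmnist")
    }


@pytest.fixture(scope="session")
def trained_multi(small_dataset):
    """One multimodal model at desk scale (12 epochs on 720 train pairs)."""
    cfg = TrainConfig(mode="multi", epochs=12, seeds=(0,))
    model, log = train_model(cfg, small_dataset, seed=0)
    return model, log


@pytest.fixture(scope="session")
def trained_single(small_dataset):
    cfg = TrainConfig(mode="single", epochs=12, seeds=(0,))
    model, log = train_model(cfg, small_dataset, seed=0)
    return model, log


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
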