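"""Latent-space arithmetic probe.

The model is never trained on arithmetic.  Three images depicting numbers
a, b, c are encoded; the combination z_a + z_b - z_c is formed OUTSIDE the
network and decoded back to an image, which an oracle classifier reads.  If
the latent geometry mirrors numerical magnitude, the decoded image should
depict a + b - c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import ConfusionMatrix, FactorClassifier
from .datasets import PairedDataset
from .mmvae import MultimodalModel, decode, encode

__all__ = [
    "Expression",
    "build_expression_set",
    "latent_arithmetic",
    "arithmetic_success_rate",
    "ArithmeticScore",
]


@dataclass(frozen=True)
class Expression:
    """a + b - c with every operand and the answer in [1, 9]."""

    a: int
    b: int
    c: int

    @property
    def answer(self) -> int:
        return self.a + self.b - self.c

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c):
            if not 1 <= v <= 9:
                raise ValueError(f"operand {v} outside [1, 9]")
        if not 1 <= self.answer <= 9:
            raise ValueError(f"answer {self.answer} outside [1, 9]")


def build_expression_set(
    n_per_answer: int | None = None,
    seed: int = 0,
) -> list[Expression]:
    """All a + b - c with operands and answer in [1, 9].

    With ``n_per_answer`` set, a seeded stratified subsample balanced over
    answers is returned (answers with fewer expressions keep all of them).
    """
    full = [
        Expression(a, b, c)
        for a in range(1, 10)
        for b in range(1, 10)
        for c in range(1, 10)
        if 1 <= a + b - c <= 9
    ]
    if n_per_answer is None:
        return full
    rng = np.random.default_rng(seed)
    out: list[Expression] = []
    for ans in range(1, 10):
        pool = [e for e in full if e.answer == ans]
        if len(pool) > n_per_answer:
            idx = rng.choice(len(pool), size=n_per_answer, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        out.extend(pool)
    return out


def latent_arithmetic(
    model: MultimodalModel,
    modality: str,
    img_a: np.ndarray,
    img_b: np.ndarray,
    img_c: np.ndarray,
) -> np.ndarray:
    """decode(z_a + z_b - z_c) using posterior means; deterministic."""
    za = encode(model, modality, img_a).loc
    zb = encode(model, modality, img_b).loc
    zc = encode(model, modality, img_c).loc
    return decode(model, modality, za + zb - zc)


@dataclass
class ArithmeticScore:
    rate: float  # fraction of decoded images classified as the true answer
    confusion: ConfusionMatrix  # rows = true answers, cols = predictions
    n_trials: int


def arithmetic_success_rate(
    model: MultimodalModel,
    classifier: FactorClassifier,
    expressions: list[Expression],
    dataset: PairedDataset,
    modality: str,
    stimuli_per_expression: int = 10,
    rng: np.random.Generator | None = None,
) -> ArithmeticScore:
    """Score the arithmetic probe over concrete image draws.

    For each expression, ``stimuli_per_expression`` triples of operand images
    are drawn from the dataset's test split (by number label), combined in
    latent space, decoded, and classified; predictions are tallied against
    the expression's answer.
    """
    if not expressions:
        raise ValueError("empty expression set")
    rng = rng or np.random.default_rng()
    test = dataset.split("test")
    images = test.oscn if modality == "oscn" else test.cmnist
    numbers = test.labels["number"].to_numpy()
    by_number = {n: np.flatnonzero(numbers == n) for n in range(1, 10)}
    for n, idx in by_number.items():
        if idx.size == 0:
            raise ValueError(f"test split has no images of number {n}")

    # encode the whole test split once; arithmetic reuses posterior means
    z_all = encode(model, modality, images).loc

    z_combined, answers = [], []
    for expr in expressions:
        for _ in range(stimuli_per_expression):
            ia = int(rng.choice(by_number[expr.a]))
            ib = int(rng.choice(by_number[expr.b]))
            ic = int(rng.choice(by_number[expr.c]))
            z_combined.append(z_all[ia] + z_all[ib] - z_all[ic])
            answers.append(expr.answer)
    generated = decode(model, modality, np.stack(z_combined))
    preds = classifier.predict(generated)
    answers = np.asarray(answers)
    classes = np.arange(1, 10)
    counts = np.zeros((9, 9), dtype=int)
    for t, p in zip(answers, preds):
        if 1 <= p <= 9:
            counts[t - 1, p - 1] += 1
    cm = ConfusionMatrix(counts=counts, classes=classes, task="arithmetic", modality=modality)
    rate = float((preds == answers).mean())
    return ArithmeticScore(rate=rate, confusion=cm, n_trials=len(answers))
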