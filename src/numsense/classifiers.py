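"""Oracle classifiers for scoring generated images.

Generated images cannot be scored by eye, so a separate classifier is
trained on clean labeled images and then applied to the model's
reconstructions and cross-generations.  The classifier is only usable as an
oracle if it is near-ceiling on clean held-out images; below the configured
floor it refuses to score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier

from .datasets import PairedDataset
from .mmvae import ModeError, MultimodalModel, cross_generate, decode, encode

__all__ = [
    "ClassifierSanityError",
    "FactorClassifier",
    "ConfusionMatrix",
    "GenerationScore",
    "train_classifier",
    "score_generation",
    "one_sample_ttest",
    "TTestResult",
]


class ClassifierSanityError(RuntimeError):
    """The oracle classifier failed its clean-accuracy floor."""


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: np.ndarray
    task: str  # "recon" | "cross" | "arithmetic"
    modality: str

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(1, self.counts.sum()))

    def per_class_accuracy(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / row_sums
        return np.where(row_sums > 0, acc, np.nan)


def _pooled(x: np.ndarray, pool: int) -> np.ndarray:
    n, h, w, c = x.shape
    hp, wp = h // pool, w // pool
    return x[:, : hp * pool, : wp * pool].reshape(n, hp, pool, wp, pool, c).mean(axis=(2, 4)).reshape(n, -1)


def _template_correlations(x: np.ndarray) -> np.ndarray:
    """Peak matched-filter response per shape template, scale-normalized."""
    from scipy import ndimage

    from .datasets import SHAPES, _shape_mask

    grey = x.sum(axis=3)
    templates = [_shape_mask(s).astype(np.float64) / 16.0 for s in SHAPES]
    out = np.zeros((len(x), len(templates)))
    for i, g in enumerate(grey):
        peak = g.max()
        if peak <= 0:
            continue
        for j, t in enumerate(templates):
            out[i, j] = ndimage.correlate(g, t, mode="constant").max() / peak
    return out


def _features(images: np.ndarray, modality: str, target_factor: str) -> np.ndarray:
    """Translation-tolerant features tailored to the factor being read out.

    Raw-pixel classifiers memorize object layouts instead of counting, so
    each factor gets the invariant cue that actually carries it:

    * object-image number — per-channel total intensity (objects have equal
      pixel area, so mass is proportional to count at color-fixed ratios);
    * digit number — channel totals plus 4x4 block-averaged maps (the glyph
      shape is global, not a repeated local token);
    * color — channel totals (the ratios identify the palette entry);
    * object shape — peak matched-filter responses of the three shape
      templates.

    These cues survive decoder blur far better than exact pixel values.
    """
    x = np.asarray(images, dtype=np.float64)
    sums = x.sum(axis=(1, 2))
    if target_factor == "color":
        return sums
    if target_factor == "number":
        if modality == "oscn":
            return sums
        return np.concatenate([sums, _pooled(x, 4)], axis=1)
    if target_factor == "shape":
        if modality != "oscn":
            raise ValueError("shape is a factor of the object modality only")
        return _template_correlations(x)
    raise ValueError(f"unknown target factor {target_factor!r}")


@dataclass
class FactorClassifier:
    """A trained image classifier for one generative factor."""

    clf: MLPClassifier
    modality: str
    target_factor: str  # "number" | "color" | "shape"
    clean_accuracy: float
    floor: float

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.clf.predict(_features(images, self.modality, self.target_factor))


def train_classifier(
    dataset: PairedDataset,
    modality: str,
    target_factor: str = "number",
    seed: int = 0,
    floor: float = 0.95,
    hidden: int = 64,
    max_iter: int = 1200,
) -> FactorClassifier:
    """Fit an MLP on the train split; validate on the clean test split.

    Raises :class:`ClassifierSanityError` if held-out clean accuracy is below
    ``floor`` — an oracle that cannot read clean images cannot score
    generated ones.
    """
    if modality not in ("oscn", "cmnist"):
        raise ValueError(f"unknown modality {modality!r}")
    if target_factor not in ("number", "color", "shape"):
        raise ValueError(f"unknown target factor {target_factor!r}")
    train, test = dataset.split("train"), dataset.split("test")
    images = train.oscn if modality == "oscn" else train.cmnist
    y = train.labels[target_factor].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"degenerate training set: only {len(np.unique(y))} class of "
            f"{target_factor!r} present; cannot train a classifier"
        )
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden, hidden),
        max_iter=max_iter,
        random_state=seed,
        early_stopping=False,
        n_iter_no_change=40,
    )
    clf.fit(_features(images, modality, target_factor), y)
    test_images = test.oscn if modality == "oscn" else test.cmnist
    y_test = test.labels[target_factor].to_numpy()
    clean_acc = float(
        (clf.predict(_features(test_images, modality, target_factor)) == y_test).mean()
    )
    if clean_acc < floor:
        raise ClassifierSanityError(
            f"clean held-out accuracy {clean_acc:.3f} below floor {floor} for "
            f"{modality}/{target_factor}; refusing to use as scoring oracle"
        )
    return FactorClassifier(
        clf=clf, modality=modality, target_factor=target_factor, clean_accuracy=clean_acc, floor=floor
    )


@dataclass
class GenerationScore:
    confusion: ConfusionMatrix
    mean_accuracy: float  # unweighted mean of per-class accuracies
    overall_accuracy: float
    task: str
    src_modality: str
    dst_modality: str


def score_generation(
    model: MultimodalModel,
    classifier: FactorClassifier,
    task: str,
    src_modality: str,
    dataset: PairedDataset,
    generate_fn=None,
) -> GenerationScore:
    """Score recon or cross generations of the test split against true numbers.

    The generation path uses the posterior mean so scoring is deterministic.
    ``generate_fn(model, images) -> images`` overrides the path (used by
    tests with identity / constant probes).
    """
    if task not in ("recon", "cross"):
        raise ValueError(f"task must be 'recon' or 'cross', got {task!r}")
    if task == "cross" and model.mode != "multi":
        raise ModeError("cross-generation scoring requires a multi-mode model")
    test = dataset.split("test")
    images = test.oscn if src_modality == "oscn" else test.cmnist
    truth = test.labels[classifier.target_factor].to_numpy()
    if task == "recon":
        dst = src_modality
    else:
        dst = "cmnist" if src_modality == "oscn" else "oscn"
    if classifier.modality != dst:
        raise ValueError(
            f"classifier reads {classifier.modality!r} images but the "
            f"generation path emits {dst!r} images"
        )
    if generate_fn is not None:
        generated = generate_fn(model, images)
    elif task == "recon":
        generated = decode(model, src_modality, encode(model, src_modality, images).loc)
    else:
        generated = cross_generate(model, src_modality, dst, images, use_mean=True)
    preds = classifier.predict(generated)
    classes = np.unique(np.concatenate([truth, preds]))
    counts = _sk_confusion(truth, preds, labels=classes)
    cm = ConfusionMatrix(counts=counts, classes=classes, task=task, modality=dst)
    per_class = cm.per_class_accuracy()
    return GenerationScore(
        confusion=cm,
        mean_accuracy=float(np.nanmean(per_class)),
        overall_accuracy=cm.accuracy,
        task=task,
        src_modality=src_modality,
        dst_modality=dst,
    )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def one_sample_ttest(values, mu0: float) -> TTestResult:
    """One-sample t-test of the mean of ``values`` against ``mu0``.

    With zero sample variance the statistic is undefined; the result is
    flagged degenerate with t = nan.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.ptp(values) == 0.0:
        return TTestResult(t=float("nan"), df=float(values.size - 1), p=float("nan"), degenerate=True)
    res = stats.ttest_1samp(values, mu0)
    return TTestResult(t=float(res.statistic), df=float(values.size - 1), p=float(res.pvalue))
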