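"""Quantitative evaluation of latent representations.

All quantitative metrics are computed in the original latent space
(posterior means); the 2-D t-SNE embedding exists only for visualization and
never feeds a number reported by this package.

* **Silhouette coefficient** per factor (number / color / shape): how tightly
  same-class latents cluster relative to the nearest other class, in [-1, 1].
* **Centroid-distance correlation** ("number line"): Pearson correlation
  between pairwise Euclidean distances of per-number centroids and the class
  difference |i - j| (or |log i - log j| for the compressed-scale variant).
  r near 1 means latent geometry mirrors numerical magnitude.
* **Welch comparisons** between per-seed metric ensembles from different
  training modes (unequal variances; fractional degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .datasets import PairedDataset
from .mmvae import MultimodalModel, encode

__all__ = [
    "LabeledLatents",
    "MetricRecord",
    "compute_latents",
    "embed_2d",
    "silhouette",
    "centroid_distance_correlation",
    "scale_comparison",
    "compare_conditions",
    "WelchResult",
]


@dataclass
class LabeledLatents:
    """Posterior-mean latent codes with parallel factor labels."""

    z: np.ndarray  # (n, latent_dim)
    labels: pd.DataFrame  # columns include number, color, shape
    modality: str
    mode: str  # training mode of the source model

    def __post_init__(self) -> None:
        if len(self.z) != len(self.labels):
            raise ValueError("latent rows and label rows must align")

    def factor(self, name: str) -> np.ndarray:
        if name not in self.labels.columns:
            raise KeyError(f"no factor {name!r} in labels")
        return self.labels[name].to_numpy()


@dataclass
class MetricRecord:
    """Per-seed, per-mode, per-modality evaluation summary."""

    seed: int
    mode: str
    modality: str
    silhouette_number: float = float("nan")
    silhouette_color: float = float("nan")
    silhouette_shape: float = float("nan")
    centroid_corr_linear: float = float("nan")
    centroid_corr_log: float = float("nan")
    recon_accuracy: float = float("nan")
    cross_accuracy: float = float("nan")
    arithmetic_success: float = float("nan")


def compute_latents(
    model: MultimodalModel, modality: str, dataset: PairedDataset, split: str = "test"
) -> LabeledLatents:
    """Posterior-mean latents of one split for one modality."""
    part = dataset.split(split)
    images = part.oscn if modality == "oscn" else part.cmnist
    post = encode(model, modality, images)
    return LabeledLatents(z=post.loc, labels=part.labels, modality=modality, mode=model.mode)


def embed_2d(z: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE map of latents to 2-D, for plotting only."""
    z = np.asarray(z, dtype=float)
    if len(z) < perplexity + 1:
        raise ValueError(f"need at least perplexity+1={perplexity + 1:.0f} points, got {len(z)}")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(z)


def silhouette(latents: LabeledLatents, factor: str = "number") -> float:
    """Mean silhouette over points, Euclidean distance in the full latent space."""
    y = latents.factor(factor)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"silhouette needs >= 2 distinct {factor!r} labels")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 points")
    return float(silhouette_score(latents.z, y, metric="euclidean"))


def centroid_distance_correlation(
    latents: LabeledLatents,
    scale: str = "linear",
    method: str = "pearson",
    factor: str = "number",
) -> float:
    """Correlation between centroid distances and class differences.

    For every pair of number classes (i, j), the Euclidean distance between
    the class-mean latents is correlated against |i - j| (linear scale) or
    |log i - log j| (log scale).
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"scale must be 'linear' or 'log', got {scale!r}")
    y = latents.factor(factor)
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("need >= 3 classes for a meaningful correlation")
    centroids = np.stack([latents.z[y == c].mean(axis=0) for c in classes])
    d_latent, d_class = [], []
    for (ia, a), (ib, b) in combinations(enumerate(classes), 2):
        d_latent.append(float(np.linalg.norm(centroids[ia] - centroids[ib])))
        if scale == "linear":
            d_class.append(abs(float(a) - float(b)))
        else:
            d_class.append(abs(np.log(float(a)) - np.log(float(b))))
    d_latent = np.asarray(d_latent)
    if np.allclose(d_latent.std(), 0.0):
        raise ValueError("identical centroids: zero variance in cluster distances")
    if method == "pearson":
        r = stats.pearsonr(d_latent, d_class).statistic
    elif method == "spearman":
        r = stats.spearmanr(d_latent, d_class).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r)


def scale_comparison(latents: LabeledLatents, method: str = "pearson") -> dict[str, float]:
    """Linear vs logarithmic number-line fit of the latent geometry."""
    return {
        "linear": centroid_distance_correlation(latents, scale="linear", method=method),
        "log": centroid_distance_correlation(latents, scale="log", method=method),
    }


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float


def compare_conditions(values_a, values_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degrees of freedom follow Welch–Satterthwaite and are fractional in
    general.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per condition")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                               mean_a=float(a.mean()), mean_b=float(b.mean()))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
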