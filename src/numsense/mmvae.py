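"""Mixture-of-experts multimodal VAE over a shared 20-d latent space.

Two modality-specific encoder/decoder pairs (object images and colored
digits) share one latent space and a standard-normal prior.  In ``multi``
mode the model is trained on the mixture-of-experts objective

    L = (1/2) * sum_m  E_{z ~ q(z | x_m)} log [ p(z) p(x_1 | z) p(x_2 | z)
                                                / q_mix(z | x_1, x_2) ]

with q_mix the equal-weight mixture of the two diagonal-Gaussian posteriors,
estimated by K-sample importance weighting per expert; every sampled latent
must reconstruct BOTH modalities, which is what couples the two spaces.  In
``single`` mode the two autoencoders are trained independently on their own
per-modality evidence lower bounds and exchange nothing.

Pixels are modelled with a fixed-scale Gaussian likelihood on the decoder
mean (a Laplace alternative is available); posteriors are diagonal Gaussians
with softplus scales.  The Gaussian is the default because its optimum is
the conditional mean: sparse object scenes then decode to images whose total
mass tracks the expected object count even when exact layout is uncertain,
whereas the L1-optimal (median) prediction collapses to the empty
background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import Linear, Tensor, logsumexp, stack

__all__ = [
    "MODALITIES",
    "ModeError",
    "PosteriorParams",
    "LatentCode",
    "MultimodalModel",
    "encode",
    "decode",
    "moe_objective",
    "single_objective",
    "cross_generate",
]

MODALITIES = ("oscn", "cmnist")

_LOG_2PI = np.log(2.0 * np.pi)


class ModeError(RuntimeError):
    """Operation requested on a model trained in the wrong mode."""


@dataclass(frozen=True)
class PosteriorParams:
    """Diagonal Gaussian posterior q(z | x) for one modality."""

    loc: np.ndarray  # (n, latent_dim)
    scale: np.ndarray  # (n, latent_dim), strictly positive
    modality: str


@dataclass(frozen=True)
class LatentCode:
    z: np.ndarray
    source_modality: str


class _Coder:
    """One modality's encoder (image -> posterior) and decoder (z -> mean image)."""

    def __init__(self, n_pixels: int, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.latent_dim = latent_dim
        self.enc1 = Linear(n_pixels, hidden, rng)
        self.enc2 = Linear(hidden, 2 * latent_dim, rng)
        self.dec1 = Linear(latent_dim, hidden, rng)
        self.dec2 = Linear(hidden, n_pixels, rng)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc1(x).relu()
        out = self.enc2(h)
        loc = out.cols(0, self.latent_dim)
        scale = out.cols(self.latent_dim, 2 * self.latent_dim).softplus() + 1e-4
        return loc, scale

    def decode(self, z: Tensor) -> Tensor:
        h = self.dec1(z).relu()
        return self.dec2(h).sigmoid()

    @property
    def params(self) -> list[Tensor]:
        return self.enc1.params + self.enc2.params + self.dec1.params + self.dec2.params


class MultimodalModel:
    """Two encoder/decoder pairs over one shared latent space.

    Parameters
    ----------
    mode:
        ``"multi"`` couples the modalities through the mixture-of-experts
        objective; ``"single"`` keeps two independent autoencoders (the
        baseline) with no latent exchange.
    latent_dim:
        Dimension of the shared latent space (default 20).
    likelihood_scale:
        Fixed scale of the per-pixel likelihood (sigma for Gaussian, b for
        Laplace).
    likelihood:
        "gaussian" (default) or "laplace".
    """

    def __init__(
        self,
        mode: str = "multi",
        latent_dim: int = 20,
        canvas_size: int = 32,
        hidden: int = 256,
        likelihood_scale: float = 0.1,
        likelihood: str = "gaussian",
        seed: int = 0,
    ):
        if mode not in ("multi", "single"):
            raise ValueError(f"mode must be 'multi' or 'single', got {mode!r}")
        if likelihood not in ("gaussian", "laplace"):
            raise ValueError(f"likelihood must be 'gaussian' or 'laplace', got {likelihood!r}")
        self.likelihood = likelihood
        self.mode = mode
        self.latent_dim = latent_dim
        self.canvas_size = canvas_size
        self.hidden = hidden
        self.likelihood_scale = likelihood_scale
        self.seed = seed
        self.n_pixels = canvas_size * canvas_size * 3
        rng = np.random.default_rng(seed)
        self.coders = {m: _Coder(self.n_pixels, latent_dim, hidden, rng) for m in MODALITIES}

    # -- parameter access --------------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        return [p for m in MODALITIES for p in self.coders[m].params]

    def param_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for m in MODALITIES:
            c = self.coders[m]
            for name in ("enc1", "enc2", "dec1", "dec2"):
                layer = getattr(c, name)
                out[f"{m}.{name}.W"] = layer.W.data
                out[f"{m}.{name}.b"] = layer.b.data
        return out

    def set_param_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for m in MODALITIES:
            c = self.coders[m]
            for name in ("enc1", "enc2", "dec1", "dec2"):
                layer = getattr(c, name)
                layer.W.data = np.asarray(arrays[f"{m}.{name}.W"], dtype=np.float64).copy()
                layer.b.data = np.asarray(arrays[f"{m}.{name}.b"], dtype=np.float64).copy()

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(
            mode=self.mode,
            latent_dim=self.latent_dim,
            canvas_size=self.canvas_size,
            hidden=self.hidden,
            likelihood_scale=self.likelihood_scale,
            likelihood=self.likelihood,
            seed=self.seed,
        )
        np.savez_compressed(path, __meta__=np.array([json.dumps(meta)]), **self.param_arrays())

    @classmethod
    def load(cls, path) -> "MultimodalModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"][0]))
            model = cls(**meta)
            model.set_param_arrays({k: f[k] for k in f.files if k != "__meta__"})
        return model

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        expected = (self.canvas_size, self.canvas_size, 3)
        if images.shape[1:] != expected:
            raise ValueError(f"expected images of shape {expected}, got {images.shape[1:]}")
        return images.reshape(images.shape[0], -1)


# --------------------------------------------------------------------------
# functional interface


def encode(model: MultimodalModel, modality: str, images: np.ndarray) -> PosteriorParams:
    """Posterior parameters for a batch of images; deterministic."""
    _check_modality(modality)
    x = Tensor(model._flatten(images))
    loc, scale = model.coders[modality].encode(x)
    return PosteriorParams(loc=loc.data.copy(), scale=scale.data.copy(), modality=modality)


def decode(model: MultimodalModel, modality: str, latent: LatentCode | np.ndarray) -> np.ndarray:
    """Mean image(s) for latent code(s); values in [0, 1]."""
    _check_modality(modality)
    z = latent.z if isinstance(latent, LatentCode) else np.asarray(latent, dtype=np.float64)
    if z.ndim == 1:
        z = z[None]
    if z.shape[-1] != model.latent_dim:
        raise ValueError(f"latent dim {z.shape[-1]} != model latent_dim {model.latent_dim}")
    out = model.coders[modality].decode(Tensor(z))
    cs = model.canvas_size
    return out.data.reshape(-1, cs, cs, 3)


def _gauss_logpdf(z: Tensor, loc: Tensor, scale: Tensor) -> Tensor:
    """Sum over latent dims of the diagonal-Gaussian log density; (batch,)."""
    u = (z - loc) / scale
    return (-0.5 * (u * u) - scale.log() - 0.5 * _LOG_2PI).sum(axis=1)


def _std_normal_logpdf(z: Tensor) -> Tensor:
    return (-0.5 * (z * z) - 0.5 * _LOG_2PI).sum(axis=1)


def _laplace_loglik(x: Tensor, mean: Tensor, b: float) -> Tensor:
    return (-(x - mean).abs() / b - np.log(2.0 * b)).sum(axis=1)


def _pixel_loglik(model: "MultimodalModel", x: Tensor, mean: Tensor) -> Tensor:
    s = model.likelihood_scale
    if model.likelihood == "laplace":
        return _laplace_loglik(x, mean, s)
    u = (x - mean) * (1.0 / s)
    return (-0.5 * (u * u) - np.log(s) - 0.5 * _LOG_2PI).sum(axis=1)


def moe_objective(
    model: MultimodalModel,
    oscn_batch: np.ndarray,
    cmnist_batch: np.ndarray,
    K: int = 1,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """K-sample importance-weighted mixture-of-experts bound (scalar Tensor).

    For each modality expert, K reparameterized latents are drawn from that
    expert's posterior; each latent scores the joint p(z, x_oscn, x_cmnist)
    against the mixture posterior, so both decoders see every latent (the
    reconstruction and the cross paths).  The returned scalar is the batch
    mean and is gradient-compatible.
    """
    if model.mode != "multi":
        raise ModeError("moe_objective requires a multi-mode model")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = rng or np.random.default_rng()
    xs = {
        "oscn": Tensor(model._flatten(oscn_batch)),
        "cmnist": Tensor(model._flatten(cmnist_batch)),
    }
    post = {m: model.coders[m].encode(xs[m]) for m in MODALITIES}
    total = None
    for m in MODALITIES:
        loc_m, scale_m = post[m]
        log_ws = []
        for _ in range(K):
            eps = Tensor(rng.standard_normal(loc_m.shape))
            z = loc_m + scale_m * eps
            lw = _std_normal_logpdf(z)
            for j in MODALITIES:
                lw = lw + _pixel_loglik(model, xs[j], model.coders[j].decode(z))
            comp = stack([_gauss_logpdf(z, *post[j]) for j in MODALITIES], axis=0)
            log_q_mix = logsumexp(comp, axis=0) - np.log(len(MODALITIES))
            log_ws.append(lw - log_q_mix)
        if K == 1:
            l_m = log_ws[0]
        else:
            l_m = logsumexp(stack(log_ws, axis=0), axis=0) - np.log(K)
        total = l_m if total is None else total + l_m
    return (total / len(MODALITIES)).mean()


def single_objective(
    model: MultimodalModel,
    batch: np.ndarray,
    modality: str,
    K: int = 1,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Per-modality K-sample evidence lower bound; no cross-modal terms."""
    if model.mode != "single":
        raise ModeError("single_objective requires a single-mode model")
    _check_modality(modality)
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = rng or np.random.default_rng()
    x = Tensor(model._flatten(batch))
    loc, scale = model.coders[modality].encode(x)
    log_ws = []
    for _ in range(K):
        eps = Tensor(rng.standard_normal(loc.shape))
        z = loc + scale * eps
        lw = (
            _std_normal_logpdf(z)
            + _pixel_loglik(model, x, model.coders[modality].decode(z))
            - _gauss_logpdf(z, loc, scale)
        )
        log_ws.append(lw)
    if K == 1:
        l = log_ws[0]
    else:
        l = logsumexp(stack(log_ws, axis=0), axis=0) - np.log(K)
    return l.mean()


def cross_generate(
    model: MultimodalModel,
    src_modality: str,
    dst_modality: str,
    images: np.ndarray,
    use_mean: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Encode with one modality, decode with the other.

    With ``use_mean`` the posterior mean is used and the map is deterministic;
    otherwise one reparameterized sample is drawn.
    """
    if model.mode != "multi":
        raise ModeError("cross_generate requires a multi-mode model")
    _check_modality(src_modality)
    _check_modality(dst_modality)
    post = encode(model, src_modality, images)
    if use_mean:
        z = post.loc
    else:
        rng = rng or np.random.default_rng()
        z = post.loc + post.scale * rng.standard_normal(post.loc.shape)
    return decode(model, dst_modality, z)


def _check_modality(modality: str) -> None:
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
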