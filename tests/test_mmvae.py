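"""Model contracts and an independent re-computation of both objectives.

The estimator oracle re-implements the forward pass and the importance
weights in plain NumPy (no Tensor graph), replaying the identical noise
draws, and must agree with the packaged objective to float precision.
"""

from __future__ import annotations

import numpy as np
import pytest

from numsense.mmvae import (
    MODALITIES,
    ModeError,
    MultimodalModel,
    cross_generate,
    decode,
    encode,
    moe_objective,
    single_objective,
)

LOG_2PI = np.log(2.0 * np.pi)


@pytest.fixture(scope="module")
def toy_batch():
    rng = np.random.default_rng(0)
    oscn = rng.uniform(0, 1, size=(3, 16, 16, 3))
    cmnist = rng.uniform(0, 1, size=(3, 16, 16, 3))
    return oscn, cmnist


@pytest.fixture(scope="module")
def multi_model():
    return MultimodalModel(mode="multi", latent_dim=4, hidden=8, canvas_size=16, seed=1)


@pytest.fixture(scope="module")
def single_model():
    return MultimodalModel(mode="single", latent_dim=4, hidden=8, canvas_size=16, seed=1)


# -- independent NumPy forward ------------------------------------------------


def np_encode(model, modality, x_flat):
    c = model.coders[modality]
    h = np.maximum(x_flat @ c.enc1.W.data + c.enc1.b.data, 0.0)
    out = h @ c.enc2.W.data + c.enc2.b.data
    d = model.latent_dim
    loc = out[:, :d]
    s = out[:, d:]
    scale = np.maximum(s, 0) + np.log1p(np.exp(-np.abs(s))) + 1e-4
    return loc, scale

def np_decode(model, modality, z):
    c = model.coders[modality]
    h = np.maximum(z @ c.dec1.W.data + c.dec1.b.data, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ c.dec2.W.data + c.dec2.b.data)))

def np_gauss_logpdf(z, loc, scale):
    return (-0.5 * ((z - loc) / scale) ** 2 - np.log(scale) - 0.5 * LOG_2PI).sum(axis=1)

def np_pixel_loglik(model, x, mean):
    s = model.likelihood_scale
    if model.likelihood == "laplace":
        return (-np.abs(x - mean) / s - np.log(2 * s)).sum(axis=1)
    return (-0.5 * ((x - mean) / s) ** 2 - np.log(s) - 0.5 * LOG_2PI).sum(axis=1)


def np_moe_objective(model, oscn, cmnist, K, seed):
    """Brute-force estimator replaying the same rng draws."""
    rng = np.random.default_rng(seed)
    xs = {"oscn": oscn.reshape(len(oscn), -1), "cmnist": cmnist.reshape(len(cmnist), -1)}
    post = {m: np_encode(model, m, xs[m]) for m in MODALITIES}
    total = 0.0
    for m in MODALITIES:
        loc, scale = post[m]
        lws = []
        for _ in range(K):
            z = loc + scale * rng.standard_normal(loc.shape)
            lw = (-0.5 * z**2 - 0.5 * LOG_2PI).sum(axis=1)
            for j in MODALITIES:
                lw = lw + np_pixel_loglik(model, xs[j], np_decode(model, j, z))
            comps = np.stack([np_gauss_logpdf(z, *post[j]) for j in MODALITIES])
            m_max = comps.max(axis=0)
            log_q_mix = m_max + np.log(np.exp(comps - m_max).sum(axis=0)) - np.log(2)
            lws.append(lw - log_q_mix)
        lws = np.stack(lws)
        m_max = lws.max(axis=0)
        l_m = m_max + np.log(np.exp(lws - m_max).sum(axis=0)) - np.log(K)
        total = total + l_m
    return float((total / 2).mean())


# -- encode / decode contracts ------------------------------------------------


class TestEncodeDecode:
    def test_posterior_scale_positive_and_finite(self, multi_model, toy_batch):
        post = encode(multi_model, "oscn", toy_batch[0])
        assert np.all(post.scale > 0)
        assert np.all(np.isfinite(post.loc)) and np.all(np.isfinite(post.scale))
        assert post.loc.shape == (3, 4)

    def test_encode_deterministic(self, multi_model, toy_batch):
        a = encode(multi_model, "cmnist", toy_batch[1])
        b = encode(multi_model, "cmnist", toy_batch[1])
        assert np.array_equal(a.loc, b.loc) and np.array_equal(a.scale, b.scale)

    def test_decode_zero_latent_valid_image(self, multi_model):
        img = decode(multi_model, "oscn", np.zeros(4))
        assert img.shape == (1, 16, 16, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_decode_deterministic(self, multi_model):
        z = np.random.default_rng(1).standard_normal(4)
        assert np.array_equal(decode(multi_model, "oscn", z), decode(multi_model, "oscn", z))

    def test_shape_mismatch_errors(self, multi_model):
        with pytest.raises(ValueError):
            encode(multi_model, "oscn", np.zeros((2, 8, 8, 3)))
        with pytest.raises(ValueError):
            decode(multi_model, "oscn", np.zeros(7))
        with pytest.raises(ValueError):
            encode(multi_model, "voice", np.zeros((1, 16, 16, 3)))


# -- objectives ---------------------------------------------------------------


class TestObjectives:
    @pytest.mark.parametrize("K", [1, 3])
    def test_moe_matches_numpy_bruteforce(self, multi_model, toy_batch, K):
        seed = 99
        est = moe_objective(multi_model, *toy_batch, K=K, rng=np.random.default_rng(seed))
        expected = np_moe_objective(multi_model, *toy_batch, K=K, seed=seed)
        assert float(est.data) == pytest.approx(expected, rel=1e-10)

    def test_single_matches_numpy_bruteforce(self, single_model, toy_batch):
        seed = 5
        est = single_objective(single_model, toy_batch[0], "oscn", K=1,
                               rng=np.random.default_rng(seed))
        rng = np.random.default_rng(seed)
        x = toy_batch[0].reshape(3, -1)
        loc, scale = np_encode(single_model, "oscn", x)
        z = loc + scale * rng.standard_normal(loc.shape)
        lw = (
            (-0.5 * z**2 - 0.5 * LOG_2PI).sum(axis=1)
            + np_pixel_loglik(single_model, x, np_decode(single_model, "oscn", z))
            - np_gauss_logpdf(z, loc, scale)
        )
        assert float(est.data) == pytest.approx(float(lw.mean()), rel=1e-10)

    def test_objectives_finite_at_random_init(self, multi_model, single_model, toy_batch):
        a = moe_objective(multi_model, *toy_batch, K=2, rng=np.random.default_rng(0))
        b = single_objective(single_model, toy_batch[1], "cmnist", rng=np.random.default_rng(0))
        assert np.isfinite(a.data) and np.isfinite(b.data)

    def test_mode_errors(self, multi_model, single_model, toy_batch):
        with pytest.raises(ModeError):
            moe_objective(single_model, *toy_batch)
        with pytest.raises(ModeError):
            single_objective(multi_model, toy_batch[0], "oscn")
        with pytest.raises(ModeError):
            cross_generate(single_model, "oscn", "cmnist", toy_batch[0])

    def test_estimator_variance_decreases_with_K(self, multi_model, toy_batch):
        def estimates(K, n=25):
            return [
                float(moe_objective(multi_model, *toy_batch, K=K,
                                    rng=np.random.default_rng(1000 + i)).data)
                for i in range(n)
            ]

        v1 = np.var(estimates(1))
        v8 = np.var(estimates(8))
        assert v8 < v1

    def test_single_mode_gradient_isolation(self, single_model, toy_batch):
        """One modality's loss produces zero gradient on the other's params."""
        for p in single_model.params:
            p.grad = None
        loss = -single_objective(single_model, toy_batch[0], "oscn",
                                 rng=np.random.default_rng(0))
        loss.backward()
        for p in single_model.coders["cmnist"].params:
            assert p.grad is None or np.allclose(p.grad, 0.0)
        touched = [p for p in single_model.coders["oscn"].params if p.grad is not None]
        assert any(np.abs(p.grad).max() > 0 for p in touched)


# -- cross generation ---------------------------------------------------------


class TestCrossGenerate:
    def test_same_modality_equals_reconstruction(self, multi_model, toy_batch):
        rec = decode(multi_model, "oscn", encode(multi_model, "oscn", toy_batch[0]).loc)
        crs = cross_generate(multi_model, "oscn", "oscn", toy_batch[0])
        assert np.allclose(rec, crs)

    def test_mean_latent_deterministic(self, multi_model, toy_batch):
        a = cross_generate(multi_model, "oscn", "cmnist", toy_batch[0])
        b = cross_generate(multi_model, "oscn", "cmnist", toy_batch[0])
        assert np.array_equal(a, b)

    def test_sampled_latents_vary(self, multi_model, toy_batch):
        a = cross_generate(multi_model, "oscn", "cmnist", toy_batch[0], use_mean=False,
                           rng=np.random.default_rng(0))
        b = cross_generate(multi_model, "oscn", "cmnist", toy_batch[0], use_mean=False,
                           rng=np.random.default_rng(1))
        assert not np.array_equal(a, b)


def test_save_load_round_trip(tmp_path, multi_model, toy_batch):
    path = tmp_path / "model.npz"
    multi_model.save(path)
    back = MultimodalModel.load(path)
    assert back.mode == multi_model.mode and back.latent_dim == multi_model.latent_dim
    a = encode(multi_model, "oscn", toy_batch[0])
    b = encode(back, "oscn", toy_batch[0])
    assert np.array_equal(a.loc, b.loc)
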