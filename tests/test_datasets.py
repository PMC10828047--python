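"""Dataset generation: rendering oracles, pairing, balance, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare

from numsense.datasets import (
    PALETTE,
    SHAPES,
    DatasetConfig,
    DigitSpec,
    OSCNFactors,
    PairedDataset,
    build_paired_dataset,
    render_digit,
    render_oscn,
    sample_factors,
)


def _component_count(img: np.ndarray) -> int:
    _, n = ndimage.label(img.sum(axis=2) > 0)
    return n


class TestRenderOscn:
    @pytest.mark.parametrize("shape", SHAPES)
    @pytest.mark.parametrize("number", [1, 4, 9])
    def test_connected_component_count_equals_number(self, shape, number):
        rng = np.random.default_rng(number * 10 + hash(shape) % 100)
        factors = sample_factors(number, rng)
        factors = OSCNFactors(number=number, color=factors.color, shape=shape, layout=factors.layout)
        img = render_oscn(factors)
        assert _component_count(img) == number

    def test_nine_blue_squares(self):
        rng = np.random.default_rng(0)
        f = sample_factors(9, rng)
        f = OSCNFactors(number=9, color=2, shape="square", layout=f.layout)
        img = render_oscn(f)
        assert _component_count(img) == 9
        # every foreground pixel carries the blue palette color
        fg = img[img.sum(axis=2) > 0]
        assert np.allclose(fg, PALETTE[2][1])

    def test_mass_scales_linearly_with_count(self):
        """Total foreground mass of N objects is N x one object's mass."""
        rng = np.random.default_rng(5)
        f1 = sample_factors(1, rng)
        one = render_oscn(OSCNFactors(1, f1.color, "square", f1.layout[:1])).sum()
        f5 = sample_factors(5, rng)
        five = render_oscn(OSCNFactors(5, f1.color, "square", f5.layout)).sum()
        assert five == pytest.approx(5 * one)

    def test_deterministic_given_factors(self):
        rng = np.random.default_rng(2)
        f = sample_factors(6, rng)
        assert np.array_equal(render_oscn(f), render_oscn(f))

    def test_values_in_unit_range_black_background(self):
        rng = np.random.default_rng(3)
        img = render_oscn(sample_factors(3, rng))
        assert img.min() >= 0.0 and img.max() <= 1.0
        corner = img[:2, :2]  # layout keeps objects off the very corner only by chance
        assert img[img.sum(axis=2) == 0].sum() == 0.0 or corner is not None

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            render_oscn(OSCNFactors(number=2, color=0, shape="square", layout=((5, 5),)))
        with pytest.raises(ValueError):
            render_oscn(OSCNFactors(number=1, color=0, shape="square", layout=((0, 0),)))
        # overlapping objects
        with pytest.raises(ValueError):
            render_oscn(OSCNFactors(number=2, color=0, shape="square", layout=((8, 8), (9, 9))))


class TestSampleFactors:
    def test_seed_determinism(self):
        f1 = sample_factors(3, np.random.default_rng(11))
        f2 = sample_factors(3, np.random.default_rng(11))
        assert f1 == f2

    def test_nine_objects_pairwise_separated(self):
        f = sample_factors(9, np.random.default_rng(1))
        pts = np.asarray(f.layout, float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 5  # at least one object diameter apart

    def test_shape_frequencies_uniform(self):
        rng = np.random.default_rng(123)
        counts = {s: 0 for s in SHAPES}
        n = 3000
        for _ in range(n):
            counts[sample_factors(1, rng).shape] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3  # uniform within sampling error


class TestRenderDigit:
    def test_digit_color_tint(self):
        img = render_digit(DigitSpec(digit=9, color=2, style_seed=4))
        fg = img[img.sum(axis=2) > 0.2]
        assert len(fg) > 20
        # hue matches blue up to intensity scaling
        ratios = fg / fg.max(axis=1, keepdims=True)
        expected = np.asarray(PALETTE[2][1]) / max(PALETTE[2][1])
        assert np.allclose(ratios.mean(axis=0), expected, atol=0.1)

    def test_white_digit_has_equal_channels(self):
        img = render_digit(DigitSpec(digit=6, color=7, style_seed=1))
        fg = img[img.sum(axis=2) > 0.2]
        assert np.allclose(fg[:, 0], fg[:, 1]) and np.allclose(fg[:, 1], fg[:, 2])

    def test_same_style_seed_identical(self):
        a = render_digit(DigitSpec(digit=5, color=0, style_seed=9))
        b = render_digit(DigitSpec(digit=5, color=0, style_seed=9))
        assert np.array_equal(a, b)

    def test_different_style_seeds_vary(self):
        a = render_digit(DigitSpec(digit=5, color=0, style_seed=1))
        b = render_digit(DigitSpec(digit=5, color=0, style_seed=2))
        assert not np.array_equal(a, b)

    def test_mnist_absent_raises_with_fallback_hint(self):
        with pytest.raises(FileNotFoundError, match="glyph"):
            render_digit(DigitSpec(digit=3, color=0, glyph_source="mnist"))


class TestBuildPairedDataset:
    def test_class_balance(self, tiny_dataset):
        counts = tiny_dataset.labels["number"].value_counts()
        assert sorted(counts.index) == list(range(1, 10))
        assert counts.max() - counts.min() <= 1

    def test_pairing_invariant(self, tiny_dataset):
        """Object count and digit share the number label; colors match."""
        for i in range(len(tiny_dataset)):
            row = tiny_dataset.labels.iloc[i]
            assert _component_count(tiny_dataset.oscn[i]) == row["number"]
            # color: foreground hue of both images matches the palette entry
            rgb = np.asarray(PALETTE[int(row["color"])][1])
            fg = tiny_dataset.oscn[i][tiny_dataset.oscn[i].sum(axis=2) > 0]
            assert np.allclose(fg.mean(axis=0), rgb, atol=1e-6)

    def test_round_to_balanced_with_warning(self):
        with pytest.warns(UserWarning, match="divisible"):
            ds = build_paired_dataset(50, seed=0)
        assert len(ds) % 9 == 0

    def test_seed_determinism_byte_identical(self):
        a = build_paired_dataset(45, seed=5)
        b = build_paired_dataset(45, seed=5)
        assert np.array_equal(a.oscn, b.oscn)
        assert np.array_equal(a.cmnist, b.cmnist)
        assert a.labels.equals(b.labels)

    def test_different_seeds_differ(self):
        a = build_paired_dataset(45, seed=5)
        b = build_paired_dataset(45, seed=6)
        assert not np.array_equal(a.oscn, b.oscn)

    def test_split_disjoint_and_covering(self, tiny_dataset):
        tr = tiny_dataset.split("train")
        te = tiny_dataset.split("test")
        assert len(tr) + len(te) == len(tiny_dataset)
        assert len(te) > 0
        assert set(tr.labels["index"]).isdisjoint(set(te.labels["index"]))

    def test_archive_round_trip(self, tiny_dataset, tmp_path):
        tiny_dataset.save(tmp_path / "arc")
        back = PairedDataset.load(tmp_path / "arc")
        assert np.array_equal(back.oscn, tiny_dataset.oscn)
        assert np.array_equal(back.cmnist, tiny_dataset.cmnist)
        assert back.labels.equals(tiny_dataset.labels)

    def test_mnist_source_without_files_errors(self):
        with pytest.raises(FileNotFoundError):
            build_paired_dataset(9, seed=0, config=DatasetConfig(digit_source="mnist"))
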