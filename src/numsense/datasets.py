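"""Paired object-image / colored-digit dataset generation.

Two modalities represent the same number concept:

* **OSCN** (object--shape--color--number): an RGB canvas containing N solid
  geometric objects of one shape and one color at random non-overlapping
  positions, so numerosity is carried non-symbolically by the object count.
* **CMNIST-style digits**: an RGB image of the Arabic numeral N tinted with a
  palette color.  By default digits are rendered from a built-in vector glyph
  font with random affine jitter, so many visual patterns represent the same
  number without any external download; real MNIST IDX files can be plugged in
  instead.

Images in a pair share the number and the color; shape and layout are private
to the object modality.  Everything is deterministic under a seed.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PALETTE",
    "SHAPES",
    "OSCNFactors",
    "DigitSpec",
    "ImagePair",
    "PairedDataset",
    "DatasetConfig",
    "PlacementError",
    "render_oscn",
    "sample_factors",
    "render_digit",
    "build_paired_dataset",
]

# 8 maximally distinct colors; indices are the color labels used everywhere.
PALETTE: dict[int, tuple[str, tuple[float, float, float]]] = {
    0: ("red", (1.0, 0.15, 0.15)),
    1: ("green", (0.15, 1.0, 0.15)),
    2: ("blue", (0.25, 0.35, 1.0)),
    3: ("yellow", (1.0, 1.0, 0.2)),
    4: ("magenta", (1.0, 0.25, 1.0)),
    5: ("cyan", (0.2, 1.0, 1.0)),
    6: ("orange", (1.0, 0.6, 0.1)),
    7: ("white", (1.0, 1.0, 1.0)),
}

SHAPES: tuple[str, ...] = ("square", "cross", "triangle")

NUMBER_CLASSES: tuple[int, ...] = tuple(range(1, 10))

OBJECT_EXTENT = 5  # side of the bounding box of one object, in pixels


class PlacementError(RuntimeError):
    """Raised when a non-overlapping layout cannot be found."""


def _shape_mask(shape: str, extent: int = OBJECT_EXTENT) -> np.ndarray:
    """Boolean extent x extent mask of one object; each mask is 4-connected.

    Every mask covers exactly 16 pixels, so the total image mass is 16 N
    times the object color regardless of shape — numerosity is carried by a
    cue that survives decoder blur, while shape identity stays in the local
    pixel pattern (edge structure).
    """
    m = np.zeros((extent, extent), dtype=bool)
    if shape == "square":
        m[:4, :4] = True  # 16 px
    elif shape == "cross":
        m[1:3, :] = True  # fat plus: 10 + 10 - 4 = 16 px
        m[:, 1:3] = True
    elif shape == "triangle":
        for r, width in enumerate((1, 2, 3, 5, 5)):  # 16 px
            lo = (extent - width) // 2
            m[r, lo : lo + width] = True
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return m


@dataclass(frozen=True)
class OSCNFactors:
    """Generative factors of one object image."""

    number: int
    color: int
    shape: str
    layout: tuple[tuple[int, int], ...]  # object centers, (row, col)

    def validate(self, canvas_size: int) -> None:
        if not 1 <= self.number <= 9:
            raise ValueError(f"number must be in [1, 9], got {self.number}")
        if self.color not in PALETTE:
            raise ValueError(f"unknown color index {self.color}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if len(self.layout) != self.number:
            raise ValueError("layout length must equal number")
        half = OBJECT_EXTENT // 2
        for r, c in self.layout:
            if not (half <= r <= canvas_size - 1 - half and half <= c <= canvas_size - 1 - half):
                raise ValueError(f"object at ({r}, {c}) not fully inside canvas")
        pts = np.asarray(self.layout, dtype=float)
        if len(pts) > 1:
            d = np.abs(pts[:, None, :] - pts[None, :, :]).max(axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < OBJECT_EXTENT + 1:
                raise ValueError("objects overlap or touch")


@dataclass(frozen=True)
class DigitSpec:
    """Specification of one colored-digit image."""

    digit: int
    color: int
    glyph_source: str = "synthetic_glyph"  # or "mnist"
    style_seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.digit <= 9:
            raise ValueError(f"digit must be in [1, 9], got {self.digit}")
        if self.color not in PALETTE:
            raise ValueError(f"unknown color index {self.color}")
        if self.glyph_source not in ("synthetic_glyph", "mnist"):
            raise ValueError(f"unknown glyph source {self.glyph_source!r}")


@dataclass(frozen=True)
class ImagePair:
    oscn_image: np.ndarray  # H x W x 3 in [0, 1]
    cmnist_image: np.ndarray
    number_label: int
    color_label: int
    shape_label: str
    split: str  # "train" | "test"


def render_oscn(factors: OSCNFactors, canvas_size: int = 32) -> np.ndarray:
    """Render N solid objects of one shape and color on a black canvas.

    Deterministic function of ``factors``; the connected-component count of
    the foreground always equals ``factors.number``.
    """
    factors.validate(canvas_size)
    img = np.zeros((canvas_size, canvas_size, 3), dtype=np.float32)
    mask = _shape_mask(factors.shape)
    rgb = np.asarray(PALETTE[factors.color][1], dtype=np.float32)
    half = OBJECT_EXTENT // 2
    for r, c in factors.layout:
        patch = img[r - half : r + half + 1, c - half : c + half + 1]
        patch[mask] = rgb
    return img


def sample_factors(
    number: int,
    rng: np.random.Generator,
    canvas_size: int = 32,
    max_restarts: int = 100,
) -> OSCNFactors:
    """Draw uniform shape and color plus a rejection-sampled layout.

    Object centers are at least OBJECT_EXTENT + 1 apart in Chebyshev
    distance, so bounding boxes neither overlap nor touch.
    """
    if not 1 <= number <= 9:
        raise ValueError(f"number must be in [1, 9], got {number}")
    shape = SHAPES[int(rng.integers(len(SHAPES)))]
    color = int(rng.integers(len(PALETTE)))
    half = OBJECT_EXTENT // 2
    lo, hi = half, canvas_size - 1 - half
    min_sep = OBJECT_EXTENT + 1
    for _ in range(max_restarts):
        centers: list[tuple[int, int]] = []
        ok = True
        for _ in range(number):
            placed = False
            for _ in range(100):
                r = int(rng.integers(lo, hi + 1))
                c = int(rng.integers(lo, hi + 1))
                if all(max(abs(r - pr), abs(c - pc)) >= min_sep for pr, pc in centers):
                    centers.append((r, c))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return OSCNFactors(number=number, color=color, shape=shape, layout=tuple(centers))
    raise PlacementError(
        f"could not place {number} non-overlapping objects on a "
        f"{canvas_size}x{canvas_size} canvas after {max_restarts} restarts"
    )


# --------------------------------------------------------------------------
# digit rendering

# 5x7 bitmap glyphs for 1..9; '#' = on.
_GLYPHS = {
    1: ["..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."],
    2: [".###.", "#...#", "....#", "...#.", "..#..", ".#...", "#####"],
    3: [".###.", "#...#", "....#", "..##.", "....#", "#...#", ".###."],
    4: ["...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."],
    5: ["#####", "#....", "####.", "....#", "....#", "#...#", ".###."],
    6: [".###.", "#....", "#....", "####.", "#...#", "#...#", ".###."],
    7: ["#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."],
    8: [".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."],
    9: [".###.", "#...#", "#...#", ".####", "....#", "....#", ".###."],
}


def _glyph_bitmap(digit: int) -> np.ndarray:
    rows = _GLYPHS[digit]
    return np.array([[ch == "#" for ch in row] for row in rows], dtype=np.float32)


def _render_glyph(digit: int, canvas_size: int, rng: np.random.Generator) -> np.ndarray:
    """Grey glyph with random affine jitter (rotation, scale, shear, shift)."""
    bm = _glyph_bitmap(digit)
    zoom = canvas_size / 10.0  # base glyph occupies roughly 70% of the canvas
    big = np.kron(bm, np.ones((int(round(2 * zoom)), int(round(1.6 * zoom))), dtype=np.float32))
    canvas = np.zeros((canvas_size * 2, canvas_size * 2), dtype=np.float32)
    r0 = canvas.shape[0] // 2 - big.shape[0] // 2
    c0 = canvas.shape[1] // 2 - big.shape[1] // 2
    canvas[r0 : r0 + big.shape[0], c0 : c0 + big.shape[1]] = big

    theta = rng.uniform(-0.18, 0.18)  # ~±10 degrees
    scale = rng.uniform(0.85, 1.1)
    shear = rng.uniform(-0.15, 0.15)
    shift = rng.uniform(-2.0, 2.0, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    mat = (rot @ shr) / scale
    center = np.array(canvas.shape, dtype=float) / 2.0
    offset = center - mat @ (center + shift)
    out = ndimage.affine_transform(canvas, mat, offset=offset, order=1, mode="constant")
    # crop the central canvas_size window
    s = canvas_size // 2
    out = out[s : s + canvas_size, s : s + canvas_size]
    return np.clip(out, 0.0, 1.0)


def load_mnist_idx(images_path: str | Path) -> np.ndarray:
    """Read an MNIST IDX3 image file into a (n, 28, 28) float array in [0, 1]."""
    data = Path(images_path).read_bytes()
    magic, n, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != 2051:
        raise ValueError(f"{images_path} is not an IDX3 image file (magic={magic})")
    arr = np.frombuffer(data, dtype=np.uint8, offset=16).reshape(n, rows, cols)
    return arr.astype(np.float32) / 255.0


def render_digit(
    spec: DigitSpec,
    canvas_size: int = 32,
    mnist_images: np.ndarray | None = None,
    mnist_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Render the digit tinted with its palette color on a black canvas."""
    spec.validate()
    rng = np.random.default_rng(spec.style_seed)
    if spec.glyph_source == "mnist":
        if mnist_images is None or mnist_labels is None:
            raise FileNotFoundError(
                "MNIST glyphs requested but no IDX arrays supplied; pass "
                "mnist_images/mnist_labels loaded via load_mnist_idx, or use "
                "glyph_source='synthetic_glyph' for the built-in renderer"
            )
        idx = np.flatnonzero(mnist_labels == spec.digit)
        if idx.size == 0:
            raise ValueError(f"no MNIST example of digit {spec.digit}")
        grey = mnist_images[idx[int(rng.integers(idx.size))]]
        if grey.shape[0] != canvas_size:
            z = canvas_size / grey.shape[0]
            grey = ndimage.zoom(grey, z, order=1)
            grey = np.clip(grey[:canvas_size, :canvas_size], 0.0, 1.0)
    else:
        grey = _render_glyph(spec.digit, canvas_size, rng)
    rgb = np.asarray(PALETTE[spec.color][1], dtype=np.float32)
    return (grey[:, :, None] * rgb[None, None, :]).astype(np.float32)


# --------------------------------------------------------------------------
# paired dataset


@dataclass
class DatasetConfig:
    canvas_size: int = 32
    test_fraction: float = 0.2
    digit_source: str = "synthetic_glyph"
    mnist_images_path: str | None = None
    mnist_labels_path: str | None = None


@dataclass
class PairedDataset:
    """Arrays for both modalities plus a label table.

    ``labels`` columns: index, number, color, shape, split.  Row i of the
    label table describes row i of both image arrays.
    """

    oscn: np.ndarray  # (n, H, W, 3) float32
    cmnist: np.ndarray
    labels: pd.DataFrame
    config: DatasetConfig = field(default_factory=DatasetConfig)

    def __len__(self) -> int:
        return len(self.labels)

    def split(self, which: str) -> "PairedDataset":
        mask = (self.labels["split"] == which).to_numpy()
        return PairedDataset(
            oscn=self.oscn[mask],
            cmnist=self.cmnist[mask],
            labels=self.labels[mask].reset_index(drop=True),
            config=self.config,
        )

    def pairs(self):
        for i in range(len(self)):
            row = self.labels.iloc[i]
            yield ImagePair(
                oscn_image=self.oscn[i],
                cmnist_image=self.cmnist[i],
                number_label=int(row["number"]),
                color_label=int(row["color"]),
                shape_label=str(row["shape"]),
                split=str(row["split"]),
            )

    # -- archive -----------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for split_name in ("train", "test"):
            mask = (self.labels["split"] == split_name).to_numpy()
            np.savez_compressed(out / f"oscn_{split_name}.npz", images=self.oscn[mask])
            np.savez_compressed(out / f"cmnist_{split_name}.npz", images=self.cmnist[mask])
        self.labels.to_csv(out / "labels.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, in_dir: str | Path, config: DatasetConfig | None = None) -> "PairedDataset":
        src = Path(in_dir)
        labels = pd.read_csv(src / "labels.tsv", sep="\t")
        oscn_parts, cmnist_parts, order = [], [], []
        for split_name in ("train", "test"):
            mask = (labels["split"] == split_name).to_numpy()
            order.append(np.flatnonzero(mask))
            oscn_parts.append(np.load(src / f"oscn_{split_name}.npz")["images"])
            cmnist_parts.append(np.load(src / f"cmnist_{split_name}.npz")["images"])
        n = len(labels)
        oscn = np.empty((n, *oscn_parts[0].shape[1:]), dtype=np.float32)
        cmnist = np.empty_like(oscn)
        for idx, o, c in zip(order, oscn_parts, cmnist_parts):
            oscn[idx] = o
            cmnist[idx] = c
        return cls(oscn=oscn, cmnist=cmnist, labels=labels, config=config or DatasetConfig())


def build_paired_dataset(
    n_pairs: int,
    seed: int,
    config: DatasetConfig | None = None,
) -> PairedDataset:
    """Build a balanced paired dataset.

    Numbers 1..9 are balanced (n_pairs is rounded to a multiple of 9 with a
    warning when needed); each pair shares its number and color labels across
    modalities, while the object shape and layout are private to the object
    modality.  The train/test split is stratified by number.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    config = config or DatasetConfig()
    per_class = max(1, round(n_pairs / 9))
    if per_class * 9 != n_pairs:
        warnings.warn(
            f"n_pairs={n_pairs} not divisible by 9; using {per_class * 9} "
            f"({per_class} per number class)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    mnist_images = mnist_labels = None
    if config.digit_source == "mnist":
        if not config.mnist_images_path or not config.mnist_labels_path:
            raise FileNotFoundError(
                "digit_source='mnist' requires mnist_images_path and "
                "mnist_labels_path; use digit_source='synthetic_glyph' for the "
                "built-in renderer"
            )
        mnist_images = load_mnist_idx(config.mnist_images_path)
        raw = Path(config.mnist_labels_path).read_bytes()
        magic, n = struct.unpack(">II", raw[:8])
        if magic != 2049:
            raise ValueError("labels file is not IDX1")
        mnist_labels = np.frombuffer(raw, dtype=np.uint8, offset=8)

    cs = config.canvas_size
    rows = []
    oscn_imgs, cmnist_imgs = [], []
    n_test = int(round(per_class * config.test_fraction))
    i = 0
    for number in NUMBER_CLASSES:
        split_flags = np.array(["train"] * (per_class - n_test) + ["test"] * n_test)
        rng.shuffle(split_flags)
        for j in range(per_class):
            factors = sample_factors(number, rng, canvas_size=cs)
            spec = DigitSpec(
                digit=number,
                color=factors.color,
                glyph_source=config.digit_source,
                style_seed=int(rng.integers(2**31 - 1)),
            )
            oscn_imgs.append(render_oscn(factors, canvas_size=cs))
            cmnist_imgs.append(
                render_digit(spec, canvas_size=cs, mnist_images=mnist_images, mnist_labels=mnist_labels)
            )
            rows.append(
                {
                    "index": i,
                    "number": number,
                    "color": factors.color,
                    "shape": factors.shape,
                    "split": split_flags[j],
                }
            )
            i += 1
    labels = pd.DataFrame(rows)
    return PairedDataset(
        oscn=np.stack(oscn_imgs),
        cmnist=np.stack(cmnist_imgs),
        labels=labels,
        config=config,
    )
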