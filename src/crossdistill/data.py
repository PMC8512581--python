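"""Dual-modality dataset construction.

A "dual-modality" sample pairs an original-modality image (single channel,
what the old sensor saw) with a new-modality image (three channels, what the
upgraded sensor sees) under one ground-truth label.  Three constructions are
provided:

* **2cMNIST** — MNIST digits colored per class with one of two
  luminance-matched colors (blue ``#61a4e4`` for digits 0,3,4,7,8; green
  ``#0aef46`` for 1,2,5,6,9).  Because both colors have BT.601 luminance
  151.263, the color channel is invisible in grayscale: the original
  modality carries strictly less information.
* **grayscale/color CIFAR pairing** — the color image is the new modality,
  its BT.601 grayscale the original one.
* **a synthetic fixture** — procedurally generated shape classes emulating
  the 2cMNIST structure (confusable class pairs disambiguated only by a
  luminance-neutral color), requiring no downloads.

Class-imbalance samplers reproduce the benchmark's two imbalance profiles: a
mild linear one for the teacher (fractions 1.00 down to 0.50) and a heavy
quadratic one for the student ((1-i)^2 for i = 0, 0.1, ..., 0.9).
"""

from __future__ import annotations

import gzip
import json
import pickle
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BT601_WEIGHTS",
    "ColorPalette",
    "DualModalityDataset",
    "ImbalanceProfile",
    "default_2c_palette",
    "hex_to_rgb",
    "bt601_luminance",
    "colorize_digit",
    "rgb_to_grayscale",
    "sample_subset",
    "sample_imbalanced_subset",
    "generate_synthetic_dual_modality",
    "read_idx",
    "write_idx",
    "read_cifar10_binary_batch",
    "read_cifar10_pickle_batch",
    "load_mnist_2c",
    "load_cifar_pair",
    "export_dataset",
]

BT601_WEIGHTS = (0.299, 0.587, 0.114)

BLUE_HEX = "#61a4e4"
GREEN_HEX = "#0aef46"
BLUE_CLASSES = (0, 3, 4, 7, 8)
GREEN_CLASSES = (1, 2, 5, 6, 9)


def hex_to_rgb(hex_color: str) -> tuple[int, int, int]:
    h = hex_color.lstrip("#")
    if len(h) != 6:
        raise ValueError(f"expected a 6-digit hex color, got {hex_color!r}")
    return tuple(int(h[i:i + 2], 16) for i in (0, 2, 4))


def bt601_luminance(rgb) -> float:
    """BT.601 luma 0.299 R + 0.587 G + 0.114 B of an RGB triple."""
    r, g, b = (float(v) for v in rgb)
    return BT601_WEIGHTS[0] * r + BT601_WEIGHTS[1] * g + BT601_WEIGHTS[2] * b


@dataclass(frozen=True)
class ColorPalette:
    """Per-class RGB colors, all constrained to equal BT.601 luminance.

    Equal luminance (within 0.5 of an 8-bit level) guarantees the colors are
    indistinguishable after grayscale conversion, so colorizing adds
    information to the new modality without leaking any into the original
    one.
    """

    class_to_color: dict[int, tuple[int, int, int]]

    def __post_init__(self):
        lums = {c: bt601_luminance(rgb) for c, rgb in self.class_to_color.items()}
        lo, hi = min(lums.values()), max(lums.values())
        if hi - lo > 0.5:
            raise ValueError(
                f"palette colors must share BT.601 luminance within 0.5 "
                f"(got range {lo:.3f}..{hi:.3f})"
            )

    def color(self, label: int) -> tuple[int, int, int]:
        try:
            return self.class_to_color[int(label)]
        except KeyError:
            raise ValueError(f"label {label} not covered by palette") from None

    @property
    def n_classes(self) -> int:
        return len(self.class_to_color)


def default_2c_palette() -> ColorPalette:
    """The 2cMNIST palette: confusable digits get different colors."""
    mapping = {c: hex_to_rgb(BLUE_HEX) for c in BLUE_CLASSES}
    mapping.update({c: hex_to_rgb(GREEN_HEX) for c in GREEN_CLASSES})
    return ColorPalette(mapping)


def colorize_digit(gray_image: np.ndarray, label: int, palette: ColorPalette) -> np.ndarray:
    """Color a grayscale digit by per-channel intensity scaling.

    Output channel c is ``round(intensity / 255 * color_c)``: black background
    stays black and anti-aliased edges keep their profile.  Returns a
    (3, H, W) uint8 image for a (H, W) or (1, H, W) input.
    """
    g = np.asarray(gray_image)
    if g.ndim == 3 and g.shape[0] == 1:
        g = g[0]
    if g.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {g.shape}")
    if g.min() < 0 or g.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    rgb = palette.color(label)
    scaled = g.astype(np.float64) / 255.0
    out = np.stack([np.rint(scaled * c) for c in rgb]).astype(np.uint8)
    return out


def rgb_to_grayscale(color_image: np.ndarray) -> np.ndarray:
    """BT.601 weighted sum over channels, rounded to 8-bit.

    Accepts (3, H, W) or (H, W, 3); returns (H, W) uint8.
    """
    img = np.asarray(color_image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    if img.shape[0] == 3:
        img = img.transpose(1, 2, 0)
    elif img.shape[-1] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    lum = img @ np.asarray(BT601_WEIGHTS)
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class DualModalityDataset:
    """Paired original/new-modality images with shared labels.

    ``original``: (N, 1, H, W) uint8; ``new``: (N, 3, H, W) uint8;
    ``labels``: (N,) integer class indices in [0, n_classes).
    """

    original: np.ndarray
    new: np.ndarray
    labels: np.ndarray
    n_classes: int = 10

    def __post_init__(self):
        self.original = np.asarray(self.original, dtype=np.uint8)
        self.new = np.asarray(self.new, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.labels)
        if self.original.shape[0] != n or self.new.shape[0] != n:
            raise ValueError("modalities and labels must have equal length")
        if self.original.shape[1] != 1 or self.new.shape[1] != 3:
            raise ValueError("original modality must be 1-channel, new modality 3-channel")
        if self.original.shape[2:] != self.new.shape[2:]:
            raise ValueError("both modalities must share height and width")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels out of range")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: np.ndarray) -> "DualModalityDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return DualModalityDataset(
            self.original[idx], self.new[idx], self.labels[idx], self.n_classes
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


# ---------------------------------------------------------------------------
# subsampling


def sample_subset(dataset: DualModalityDataset, size: int, seed: int,
                  stratified: bool = False) -> DualModalityDataset:
    """Draw ``size`` samples without replacement, reproducibly under ``seed``.

    Stratified mode balances per-class counts as evenly as ``size`` allows;
    the classes receiving one extra sample (when size is not a multiple of
    the class count) are chosen by a seeded draw.
    """
    n = len(dataset)
    if size > n:
        raise ValueError(f"requested {size} samples from a dataset of {n}")
    rng = np.random.default_rng(seed)
    if not stratified:
        idx = rng.choice(n, size=size, replace=False)
        return dataset.subset(np.sort(idx))
    c = dataset.n_classes
    base, rem = divmod(size, c)
    counts = np.full(c, base, dtype=np.int64)
    if rem:
        counts[rng.choice(c, size=rem, replace=False)] += 1
    chosen = []
    for cls in range(c):
        pool = np.flatnonzero(dataset.labels == cls)
        if counts[cls] > len(pool):
            raise ValueError(
                f"class {cls} has only {len(pool)} samples, need {counts[cls]}"
            )
        chosen.append(rng.choice(pool, size=counts[cls], replace=False))
    return dataset.subset(np.sort(np.concatenate(chosen)))


@dataclass(frozen=True)
class ImbalanceProfile:
    """Per-class sampling fractions defining a long-tailed train set."""

    fractions: tuple[float, ...]
    kind: str = "custom"

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=np.float64)
        if (f <= 0).any() or (f > 1).any():
            raise ValueError("fractions must lie in (0, 1]")
        if (np.diff(f) > 1e-12).any():
            raise ValueError("fractions must be monotonically non-increasing")

    @classmethod
    def teacher_linear(cls, n_classes: int = 10) -> "ImbalanceProfile":
        """Mild imbalance: fractions linearly spaced from 1.00 down to 0.50,
        so the head class is sampled about twice as often as the tail class."""
        return cls(tuple(np.linspace(1.0, 0.5, n_classes)), kind="teacher_linear")

    @classmethod
    def student_quadratic(cls, n_classes: int = 10) -> "ImbalanceProfile":
        """Heavy imbalance: fraction (1 - i)^2 at i = 0, 0.1, ..., 0.9."""
        i = np.arange(n_classes) / n_classes
        return cls(tuple((1.0 - i) ** 2), kind="student_quadratic")

    @classmethod
    def uniform(cls, n_classes: int = 10) -> "ImbalanceProfile":
        return cls((1.0,) * n_classes, kind="uniform")


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    quota = fractions / fractions.sum() * total
    counts = np.floor(quota).astype(np.int64)
    short = total - counts.sum()
    # ties in the fractional parts resolved toward the lowest class index
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def sample_imbalanced_subset(dataset: DualModalityDataset, profile: ImbalanceProfile,
                             total: int, seed: int) -> DualModalityDataset:
    """Sample ``total`` images with per-class counts proportional to the
    profile fractions (largest-remainder rounding), reproducibly."""
    f = np.asarray(profile.fractions, dtype=np.float64)
    if len(f) != dataset.n_classes:
        raise ValueError(
            f"profile covers {len(f)} classes, dataset has {dataset.n_classes}"
        )
    counts = _largest_remainder_counts(f, total)
    rng = np.random.default_rng(seed)
    chosen = []
    for cls, k in enumerate(counts):
        pool = np.flatnonzero(dataset.labels == cls)
        if k > len(pool):
            raise ValueError(
                f"class {cls} needs {k} samples but only {len(pool)} are available"
            )
        chosen.append(rng.choice(pool, size=k, replace=False))
    return dataset.subset(np.sort(np.concatenate(chosen)))


# ---------------------------------------------------------------------------
# synthetic fixture generator


def _shape_template(shape_id: int, size: int) -> np.ndarray:
    """Deterministic grayscale template for one shape class.

    Ten distinct primitives; both members of a confusable pair share one.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2
    r = size * 0.32
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    w = max(1, size // 6)
    t = np.zeros((size, size))
    kind = shape_id % 10
    if kind == 0:  # disk
        t[d2 <= r * r] = 1.0
    elif kind == 1:  # ring
        t[(d2 <= r * r) & (d2 >= (0.55 * r) ** 2)] = 1.0
    elif kind == 2:  # plus cross
        t[(np.abs(yy - cy) <= w) | (np.abs(xx - cx) <= w)] = 1.0
        t[d2 > (size * 0.45) ** 2] = 0.0
    elif kind == 3:  # x cross
        t[(np.abs(yy - xx) <= w) | (np.abs(yy + xx - 2 * cy) <= w)] = 1.0
    elif kind == 4:  # horizontal bar
        t[np.abs(yy - cy) <= size // 5] = 1.0
    elif kind == 5:  # vertical bar
        t[np.abs(xx - cx) <= size // 5] = 1.0
    elif kind == 6:  # L-shape
        t[(xx <= w + size // 6) & (xx >= size // 6)] = 1.0
        t[(yy >= size - w - size // 6) & (yy <= size - size // 6)] = 1.0
    elif kind == 7:  # T-shape
        t[(yy <= w + size // 6) & (yy >= size // 6)] = 1.0
        t[np.abs(xx - cx) <= w] = 1.0
    elif kind == 8:  # diagonal stripes
        t[((yy + xx) % (size // 2)) < size // 5] = 1.0
    else:  # filled square
        t[(np.abs(yy - cy) <= r * 0.8) & (np.abs(xx - cx) <= r * 0.8)] = 1.0
    return t * 255.0


def generate_synthetic_dual_modality(
    n: int,
    n_classes: int = 10,
    image_size: int = 20,
    confusable_pairs: tuple[tuple[int, int], ...] | None = None,
    palette: ColorPalette | None = None,
    seed: int = 0,
    noise_sigma: float = 20.0,
    jitter: int = 2,
    stratified: bool = True,
) -> DualModalityDataset:
    """Generate paired-modality shape images emulating the 2cMNIST structure.

    Each class renders a deterministic grayscale shape (up to seeded position
    jitter, intensity scaling in [0.7, 1], and additive Gaussian noise of
    ``noise_sigma``).  Classes listed in ``confusable_pairs`` share their
    shape, so a single-channel learner cannot separate them.  The new
    modality colorizes each class with a luminance-matched palette color that
    differs within every pair, making such a pair separable only through
    color; the original modality is defined as the BT.601 grayscale of the
    new one — exactly what the old, color-blind sensor would record.

    Defaults: 10 classes with the pairs ``(0, 1)`` and ``(2, 3)`` confusable
    (the 2cMNIST construction likewise leaves most digits distinguishable in
    grayscale and uses color to resolve the hard ones), the even class of
    each pair blue and the odd one green (the 2cMNIST colors).
    """
    if confusable_pairs is None:
        confusable_pairs = tuple(
            (2 * k, 2 * k + 1) for k in range(min(2, n_classes // 2))
        )
    seen: set[int] = set()
    for a, b in confusable_pairs:
        if a in seen or b in seen or a == b:
            raise ValueError("confusable pairs must be disjoint class pairs")
        seen.update((a, b))
    if palette is None:
        blue, green = hex_to_rgb(BLUE_HEX), hex_to_rgb(GREEN_HEX)
        mapping = {}
        for a, b in confusable_pairs:
            mapping[a], mapping[b] = blue, green
        for cls in range(n_classes):
            mapping.setdefault(cls, blue)
        palette = ColorPalette(mapping)  # raises if luminance-mismatched
    if set(range(n_classes)) - set(palette.class_to_color):
        raise ValueError("palette must cover all classes")

    pair_of = {}
    for pid, (a, b) in enumerate(confusable_pairs):
        pair_of[a] = pid
        pair_of[b] = pid
    extra = len(confusable_pairs)
    for cls in range(n_classes):
        if cls not in pair_of:
            pair_of[cls] = extra
            extra += 1

    rng = np.random.default_rng(seed)
    if stratified:
        base, rem = divmod(n, n_classes)
        counts = np.full(n_classes, base, dtype=np.int64)
        if rem:
            counts[rng.choice(n_classes, size=rem, replace=False)] += 1
        labels = np.repeat(np.arange(n_classes), counts)
    else:
        labels = rng.integers(0, n_classes, size=n)
    rng.shuffle(labels)

    templates = {pid: _shape_template(pid, image_size)
                 for pid in set(pair_of.values())}
    new = np.empty((n, 3, image_size, image_size), np.uint8)
    original = np.empty((n, 1, image_size, image_size), np.uint8)
    for k, cls in enumerate(labels):
        g = templates[pair_of[int(cls)]].copy()
        dy, dx = rng.integers(-jitter, jitter + 1, size=2)
        g = np.roll(np.roll(g, dy, axis=0), dx, axis=1)
        g *= rng.uniform(0.7, 1.0)
        g += rng.normal(0.0, noise_sigma, g.shape)
        g = np.clip(g, 0, 255)
        colored = colorize_digit(g, int(cls), palette)
        new[k] = colored
        original[k, 0] = rgb_to_grayscale(colored)
    return DualModalityDataset(original, new, labels, n_classes)


# ---------------------------------------------------------------------------
# file formats

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX file (the MNIST layout: big-endian magic, dims, data)."""
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header at byte 0")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 or zero2 or dtype_code not in _IDX_DTYPES:
        raise ValueError(
            f"{path}: bad IDX magic {raw[:4].hex()} at byte 0"
        )
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise ValueError(f"{path}: truncated dimension header at byte {len(raw)}")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    dt = np.dtype(_IDX_DTYPES[dtype_code])
    expected = int(np.prod(dims)) * dt.itemsize
    body = raw[header_len:]
    if len(body) != expected:
        raise ValueError(
            f"{path}: expected {expected} data bytes, found {len(body)} "
            f"at byte {header_len}"
        )
    return np.frombuffer(body, dtype=dt).reshape(dims)


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write a uint8 array in IDX layout (for fixtures and round-trips)."""
    a = np.ascontiguousarray(array, dtype=np.uint8)
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, 0x08, a.ndim))
        fh.write(struct.pack(f">{a.ndim}I", *a.shape))
        fh.write(a.tobytes())


def read_cifar10_binary_batch(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CIFAR-10 binary batch: records of 1 label byte + 3072 pixels."""
    path = Path(path)
    raw = Path(path).read_bytes()
    rec = 1 + 3 * 32 * 32
    if len(raw) % rec:
        raise ValueError(
            f"{path}: file size {len(raw)} is not a multiple of the "
            f"{rec}-byte record (first partial record at byte {len(raw) - len(raw) % rec})"
        )
    data = np.frombuffer(raw, dtype=np.uint8).reshape(-1, rec)
    labels = data[:, 0].astype(np.int64)
    images = data[:, 1:].reshape(-1, 3, 32, 32)
    return images, labels


def read_cifar10_pickle_batch(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CIFAR-10 python pickled batch (the ``data_batch_*`` layout)."""
    with open(path, "rb") as fh:
        batch = pickle.load(fh, encoding="bytes")
    images = np.asarray(batch[b"data"], dtype=np.uint8).reshape(-1, 3, 32, 32)
    labels = np.asarray(batch[b"labels"], dtype=np.int64)
    return images, labels


def _find_mnist_file(data_dir: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz", stem.replace("-idx", ".idx"),
                 stem.replace("-idx", ".idx") + ".gz"):
        p = data_dir / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"MNIST file {stem}[.gz] not found in {data_dir}; expected the IDX "
        f"layout (train-images-idx3-ubyte etc.)"
    )


def load_mnist_2c(data_dir: str | Path, split: str = "train",
                  palette: ColorPalette | None = None) -> DualModalityDataset:
    """Build the 2cMNIST dual-modality dataset from raw MNIST IDX files.

    The grayscale digit is the original modality; the class-colored version
    (blue ``#61a4e4`` / green ``#0aef46``) is the new one.
    """
    data_dir = Path(data_dir)
    prefix = {"train": "train", "test": "t10k"}[split]
    images = read_idx(_find_mnist_file(data_dir, f"{prefix}-images-idx3-ubyte"))
    labels = read_idx(_find_mnist_file(data_dir, f"{prefix}-labels-idx1-ubyte"))
    labels = labels.astype(np.int64)
    if palette is None:
        palette = default_2c_palette()
    n = len(labels)
    new = np.empty((n, 3) + images.shape[1:], np.uint8)
    for k in range(n):
        new[k] = colorize_digit(images[k], int(labels[k]), palette)
    return DualModalityDataset(images[:, None, :, :], new, labels, 10)


def load_cifar_pair(data_dir: str | Path, split: str = "train") -> DualModalityDataset:
    """Build the grayscale/color CIFAR-10 pairing from batch files.

    Accepts either the binary (.bin) or the python-pickle batch layout.
    """
    data_dir = Path(data_dir)
    if split == "train":
        bins = [data_dir / f"data_batch_{i}.bin" for i in range(1, 6)]
        pkls = [data_dir / f"data_batch_{i}" for i in range(1, 6)]
    else:
        bins = [data_dir / "test_batch.bin"]
        pkls = [data_dir / "test_batch"]
    if all(p.exists() for p in bins):
        parts = [read_cifar10_binary_batch(p) for p in bins]
    elif all(p.exists() for p in pkls):
        parts = [read_cifar10_pickle_batch(p) for p in pkls]
    else:
        raise FileNotFoundError(
            f"CIFAR-10 batches not found in {data_dir}; expected "
            f"data_batch_*[.bin] / test_batch[.bin]"
        )
    images = np.concatenate([p[0] for p in parts])
    labels = np.concatenate([p[1] for p in parts])
    gray = np.stack([rgb_to_grayscale(img) for img in images])[:, None, :, :]
    return DualModalityDataset(gray, images, labels, 10)


# ---------------------------------------------------------------------------
# export


def export_dataset(dataset: DualModalityDataset, out_dir: str | Path,
                   split: str = "train") -> Path:
    """Write paired PNGs plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / split / "original").mkdir(parents=True, exist_ok=True)
    (out_dir / split / "new").mkdir(parents=True, exist_ok=True)
    records = []
    for k in range(len(dataset)):
        orig_path = Path(split) / "original" / f"{k:05d}.png"
        new_path = Path(split) / "new" / f"{k:05d}.png"
        Image.fromarray(dataset.original[k, 0], mode="L").save(out_dir / orig_path)
        Image.fromarray(dataset.new[k].transpose(1, 2, 0), mode="RGB").save(
            out_dir / new_path
        )
        records.append(
            {
                "id": k,
                "label": int(dataset.labels[k]),
                "original_modality": str(orig_path),
                "new_modality": str(new_path),
                "split": split,
            }
        )
    manifest = {
        "n_samples": len(dataset),
        "n_classes": dataset.n_classes,
        "class_counts": dataset.class_counts().tolist(),
        "samples": records,
    }
    manifest_path = out_dir / f"manifest_{split}.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
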