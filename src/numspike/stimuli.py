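"""Visual stimuli for the untrained-number-recognition experiments.

Three stimulus sources are provided:

* **Dot-array numerosity images** — 28x28 binary images containing 1-5
  non-overlapping circles of exactly 25 pixels each, the non-symbolic
  numerosity stimulus set (30 images per numerosity, 150 total, by default).
* **MNIST** — handwritten Arabic digits, read from the standard IDX binary
  files (the symbolic-number stimulus set).  A matching IDX writer is
  provided so small round-trip fixtures can be built without a download.
* **A synthetic digit fixture** — stroke-rendered glyphs 0-9 that emulate
  MNIST's statistical shape (28x28 grayscale in [0,1], one centered glyph,
  10 classes) so the symbolic-number pipeline runs with no download.  It is
  a test double, not a claim of MNIST equivalence.

All generators are deterministic given a seed; per-image random streams are
derived from the master seed by indexed spawning, so a dataset is
reproducible independent of generation order.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import IdxFormatError, PlacementError

IMAGE_SHAPE = (28, 28)
PIXELS_PER_ITEM = 25

#: Pixel offsets of one item: the centered disk {(dx,dy): dx^2+dy^2 <= 8.5},
#: which contains exactly 25 pixels.
DISK_OFFSETS = np.array(
    [
        (dy, dx)
        for dy in range(-2, 3)
        for dx in range(-2, 3)
        if dy * dy + dx * dx <= 8.5
    ],
    dtype=np.int64,
)

_MIN_CENTER_DIST = 6.0  # Euclidean; guarantees disjoint 25-pixel disks
_FRAME_MARGIN = 3  # item centers stay >= 3 px from the border
_MAX_ATTEMPTS = 10_000

Kind = Literal["numerosity", "digit"]

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


@dataclass(frozen=True)
class StimulusImage:
    """A 28x28 intensity grid in [0,1] with a class label.

    ``label`` is the numerosity (1-5) for dot arrays or the digit (0-9)
    for symbolic stimuli; ``kind`` says which.
    """

    pixels: np.ndarray
    label: int
    kind: Kind

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != IMAGE_SHAPE:
            raise ValueError(f"pixels must have shape {IMAGE_SHAPE}, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def foreground_count(self) -> int:
        """Number of pixels at full intensity 1.0."""
        return int(np.count_nonzero(self.pixels == 1.0))


@dataclass(frozen=True)
class StimulusDataset:
    """An ordered, class-balanced collection of stimulus images."""

    images: tuple[StimulusImage, ...]
    images_per_class: int
    seed: int
    kind: Kind

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images], dtype=np.int64)

    @property
    def class_values(self) -> np.ndarray:
        return np.unique(self.labels)


def render_numerosity_image(
    n: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> StimulusImage:
    """Render one dot-array image with exactly ``n`` disjoint 25-pixel circles.

    Item centers are drawn uniformly at random and accepted only if they
    keep every disk fully inside the frame and pairwise disjoint
    (center-to-center Euclidean distance >= 6 px, 3 px frame margin).

    Raises
    ------
    ValueError
        If ``n`` is outside 1..5.
    PlacementError
        If placement fails after 10,000 rejection attempts (never silently
        renders fewer items).
    """
    if not (1 <= n <= 5):
        raise ValueError(f"numerosity must be in 1..5, got {n}")
    rng = np.random.default_rng(seed)
    lo, hi = _FRAME_MARGIN, IMAGE_SHAPE[0] - _FRAME_MARGIN  # centers in [3, 24]
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= _MAX_ATTEMPTS:
            raise PlacementError(
                f"could not place {n} disjoint items after {_MAX_ATTEMPTS} attempts"
            )
        attempts += 1
        cand = rng.integers(lo, hi, size=2)
        if all(np.hypot(*(cand - c)) >= _MIN_CENTER_DIST for c in centers):
            centers.append(cand)
    pixels = np.zeros(IMAGE_SHAPE, dtype=np.float64)
    for c in centers:
        rows = c[0] + DISK_OFFSETS[:, 0]
        cols = c[1] + DISK_OFFSETS[:, 1]
        pixels[rows, cols] = 1.0
    return StimulusImage(pixels=pixels, label=n, kind="numerosity")


def generate_numerosity_dataset(
    images_per_class: int = 30, seed: int = 0
) -> StimulusDataset:
    """Generate the class-balanced dot-array dataset (default 5 x 30 = 150 images)."""
    if images_per_class < 1:
        raise ValueError("images_per_class must be >= 1")
    children = np.random.SeedSequence(seed).spawn(5 * images_per_class)
    images = []
    k = 0
    for label in range(1, 6):
        for _ in range(images_per_class):
            images.append(render_numerosity_image(label, children[k]))
            k += 1
    return StimulusDataset(
        images=tuple(images),
        images_per_class=images_per_class,
        seed=seed,
        kind="numerosity",
    )


# ---------------------------------------------------------------------------
# MNIST IDX format


def _read_exact(fh, nbytes: int, what: str) -> bytes:
    buf = fh.read(nbytes)
    if len(buf) != nbytes:
        raise IdxFormatError(f"truncated IDX file while reading {what}")
    return buf


def read_idx3(path: str | Path) -> np.ndarray:
    """Read an IDX3 (unsigned-byte, 3-D) image file into an (n, rows, cols) uint8 array."""
    with open(path, "rb") as fh:
        (magic,) = struct.unpack(">I", _read_exact(fh, 4, "magic number"))
        if magic != _IDX_IMAGES_MAGIC:
            raise IdxFormatError(
                f"bad magic number {magic:#010x} in {path}; "
                f"expected {_IDX_IMAGES_MAGIC:#010x} for IDX3 image data"
            )
        n, rows, cols = struct.unpack(">III", _read_exact(fh, 12, "dimensions"))
        data = _read_exact(fh, n * rows * cols, "pixel data")
        if fh.read(1):
            raise IdxFormatError(f"trailing bytes after pixel data in {path}")
    return np.frombuffer(data, dtype=np.uint8).reshape(n, rows, cols)


def read_idx1(path: str | Path) -> np.ndarray:
    """Read an IDX1 (unsigned-byte, 1-D) label file into an (n,) uint8 array."""
    with open(path, "rb") as fh:
        (magic,) = struct.unpack(">I", _read_exact(fh, 4, "magic number"))
        if magic != _IDX_LABELS_MAGIC:
            raise IdxFormatError(
                f"bad magic number {magic:#010x} in {path}; "
                f"expected {_IDX_LABELS_MAGIC:#010x} for IDX1 label data"
            )
        (n,) = struct.unpack(">I", _read_exact(fh, 4, "dimensions"))
        data = _read_exact(fh, n, "label data")
        if fh.read(1):
            raise IdxFormatError(f"trailing bytes after label data in {path}")
    return np.frombuffer(data, dtype=np.uint8)


def read_idx_images(
    images_path: str | Path, labels_path: str | Path
) -> list[StimulusImage]:
    """Read a paired IDX image/label file set (MNIST layout) as StimulusImages.

    Byte planes are scaled to [0,1] by division by 255; order is preserved.
    """
    planes = read_idx3(images_path)
    labels = read_idx1(labels_path)
    if planes.shape[0] != labels.shape[0]:
        raise IdxFormatError(
            f"image count {planes.shape[0]} in {images_path} does not match "
            f"label count {labels.shape[0]} in {labels_path}"
        )
    if planes.shape[1:] != IMAGE_SHAPE:
        raise IdxFormatError(
            f"image dimensions {planes.shape[1:]} in {images_path} are not {IMAGE_SHAPE}"
        )
    return [
        StimulusImage(pixels=plane / 255.0, label=int(lab), kind="digit")
        for plane, lab in zip(planes, labels)
    ]


def write_idx_images(
    images_path: str | Path,
    labels_path: str | Path,
    images: Sequence[StimulusImage],
) -> None:
    """Write StimulusImages as a paired IDX3/IDX1 file set (inverse of read_idx_images)."""
    planes = np.stack([np.round(im.pixels * 255.0) for im in images]).astype(np.uint8)
    labels = np.array([im.label for im in images], dtype=np.uint8)
    n, rows, cols = planes.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(planes.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, n))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# Synthetic digit fixture

# Seven-segment style glyph skeleton in (x, y) pixel coordinates.
_SEG: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "a": ((9, 5), (19, 5)),    # top
    "b": ((19, 5), (19, 14)),  # top right
    "c": ((19, 14), (19, 23)), # bottom right
    "d": ((9, 23), (19, 23)),  # bottom
    "e": ((9, 14), (9, 23)),   # bottom left
    "f": ((9, 5), (9, 14)),    # top left
    "g": ((9, 14), (19, 14)),  # middle
}
_DIGIT_SEGMENTS = {
    0: "abcdef",
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcfgd",
}


def _segment_distance(
    px: np.ndarray, py: np.ndarray, a: tuple[float, float], b: tuple[float, float]
) -> np.ndarray:
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    norm2 = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / norm2, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def render_digit_fixture(
    digit: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> StimulusImage:
    """Render a deterministic stroke glyph of ``digit`` with seed-controlled jitter.

    Jitter: integer translation of at most 2 px per axis and mild stroke
    thickness variation. Intensities are 1.0 on the stroke core with a soft
    Gaussian falloff at the edge, mimicking anti-aliased handwriting scans.
    """
    if not (0 <= digit <= 9):
        raise ValueError(f"digit must be in 0..9, got {digit}")
    rng = np.random.default_rng(seed)
    shift = rng.integers(-2, 3, size=2)  # (dx, dy), |shift| <= 2
    half_thickness = 1.0 + 0.5 * rng.random()
    ys, xs = np.mgrid[0 : IMAGE_SHAPE[0], 0 : IMAGE_SHAPE[1]]
    px = xs.astype(np.float64) - shift[0]
    py = ys.astype(np.float64) - shift[1]
    dist = np.full(IMAGE_SHAPE, np.inf)
    for seg in _DIGIT_SEGMENTS[digit]:
        dist = np.minimum(dist, _segment_distance(px, py, *_SEG[seg]))
    edge = np.clip(dist - half_thickness, 0.0, None)
    pixels = np.exp(-(edge**2) / (2 * 0.6**2))
    pixels[pixels < 1e-3] = 0.0
    return StimulusImage(pixels=pixels, label=digit, kind="digit")


def generate_digit_dataset(images_per_class: int = 30, seed: int = 0) -> StimulusDataset:
    """Generate a class-balanced synthetic digit dataset (10 classes)."""
    if images_per_class < 1:
        raise ValueError("images_per_class must be >= 1")
    children = np.random.SeedSequence(seed).spawn(10 * images_per_class)
    images = []
    k = 0
    for label in range(10):
        for _ in range(images_per_class):
            images.append(render_digit_fixture(label, children[k]))
            k += 1
    return StimulusDataset(
        images=tuple(images), images_per_class=images_per_class, seed=seed, kind="digit"
    )


def subsample_per_class(
    images: Sequence[StimulusImage], images_per_class: int, seed: int = 0
) -> list[StimulusImage]:
    """Draw a class-balanced subsample without replacement, deterministic given seed."""
    rng = np.random.default_rng(seed)
    labels = np.array([im.label for im in images])
    out: list[StimulusImage] = []
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < images_per_class:
            raise ValueError(
                f"class {label} has only {idx.size} images, need {images_per_class}"
            )
        chosen = rng.choice(idx, size=images_per_class, replace=False)
        out.extend(images[i] for i in sorted(chosen))
    return out


def export_dataset(dataset: StimulusDataset, out_dir: str | Path) -> Path:
    """Export a dataset as PNG files plus a CSV manifest; returns the manifest path."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "kind", "seed"])
        for i, im in enumerate(dataset.images):
            name = f"{im.kind}_{im.label}_{i:04d}.png"
            arr = np.round(im.pixels * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / name)
            writer.writerow([name, im.label, im.kind, dataset.seed])
    return manifest
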