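"""IDX image-file reading and seeded synthetic pattern generators.

Every pipeline stage is testable without downloads: bars-and-stripes
patterns (the classic enumerable generative-model testbed), prototype
"digits" (class prototypes plus i.i.d. pixel flips, a desk-scale stand-in
for handwritten-digit class structure), and dot-numerosity images (the
sample cognitive-modeling stimulus family). The IDX reader parses the
standard big-endian format handwritten-digit corpora are distributed in;
no download is ever performed by the library.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ImageSet",
    "read_idx",
    "write_idx",
    "load_idx_pair",
    "gen_bars_stripes",
    "gen_prototype_digits",
    "gen_dot_images",
]

_IDX_MAGIC_IMAGES = 0x00000803
_IDX_MAGIC_LABELS = 0x00000801


@dataclass
class ImageSet:
    """Vectorized image batch: n × (h·w) matrix with values in [0, 1].

    Pixels are stored row-major per image, so saved models are portable
    across readers that follow the same convention.
    """

    images: np.ndarray
    height: int
    width: int
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.images = np.atleast_2d(np.asarray(self.images, dtype=np.float64))
        if self.images.shape[1] != self.height * self.width:
            raise ValueError(
                f"vector length {self.images.shape[1]} != height*width "
                f"{self.height * self.width}"
            )
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("image values must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.shape[0] != self.images.shape[0]:
                raise ValueError("label count does not match image count")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def as_grids(self) -> np.ndarray:
        return self.images.reshape(self.n, self.height, self.width)


def _read_bytes(path: Union[str, Path]) -> bytes:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":  # gzip signature
        raw = gzip.decompress(raw)
    return raw


def read_idx(path: Union[str, Path]) -> Union[ImageSet, np.ndarray]:
    """Parse an IDX file (optionally gzip-compressed).

    Magic 0x00000803 (unsigned-byte images, 3 dims) returns an ImageSet
    with pixels scaled to [0, 1] by /255; magic 0x00000801 (labels,
    1 dim) returns an integer label vector.
    """
    raw = _read_bytes(path)
    if len(raw) < 8:
        raise ValueError(f"{path}: truncated IDX header ({len(raw)} bytes)")
    (magic,) = struct.unpack(">I", raw[:4])
    if magic == _IDX_MAGIC_IMAGES:
        if len(raw) < 16:
            raise ValueError(f"{path}: truncated IDX image header")
        n, h, w = struct.unpack(">III", raw[4:16])
        expected = 16 + n * h * w
        if len(raw) != expected:
            raise ValueError(
                f"{path}: payload size mismatch, expected {expected} bytes, got {len(raw)}"
            )
        pixels = np.frombuffer(raw, dtype=np.uint8, offset=16).astype(np.float64) / 255.0
        return ImageSet(images=pixels.reshape(n, h * w), height=h, width=w)
    if magic == _IDX_MAGIC_LABELS:
        (n,) = struct.unpack(">I", raw[4:8])
        expected = 8 + n
        if len(raw) != expected:
            raise ValueError(
                f"{path}: payload size mismatch, expected {expected} bytes, got {len(raw)}"
            )
        return np.frombuffer(raw, dtype=np.uint8, offset=8).astype(np.int64)
    raise ValueError(
        f"{path}: bad IDX magic 0x{magic:08x} (expected 0x{_IDX_MAGIC_IMAGES:08x} "
        f"for images or 0x{_IDX_MAGIC_LABELS:08x} for labels)"
    )


def write_idx(path: Union[str, Path], data: np.ndarray, kind: str = "images") -> None:
    """Write an IDX file (fixture/round-trip helper, bit-exact payload).

    ``kind="images"`` expects an (n, h, w) uint8-compatible array;
    ``kind="labels"`` a length-n integer vector.
    """
    path = Path(path)
    data = np.asarray(data)
    if kind == "images":
        if data.ndim != 3:
            raise ValueError("images must have shape (n, h, w)")
        header = struct.pack(">IIII", _IDX_MAGIC_IMAGES, *data.shape)
        payload = data.astype(np.uint8).tobytes()
    elif kind == "labels":
        header = struct.pack(">II", _IDX_MAGIC_LABELS, data.size)
        payload = data.astype(np.uint8).tobytes()
    else:
        raise ValueError("kind must be 'images' or 'labels'")
    blob = header + payload
    if path.suffix == ".gz":
        blob = gzip.compress(blob)
    path.write_bytes(blob)


def load_idx_pair(images_path: Union[str, Path], labels_path: Union[str, Path]) -> ImageSet:
    """Read a paired images + labels IDX set, checking the counts agree."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if not isinstance(images, ImageSet) or isinstance(labels, ImageSet):
        raise ValueError("expected an image file and a label file, in that order")
    if labels.shape[0] != images.n:
        raise ValueError(
            f"label count {labels.shape[0]} does not match image count {images.n}"
        )
    images.labels = labels
    return images


def _as_rows_cols(size: Union[int, tuple[int, int]]) -> tuple[int, int]:
    if isinstance(size, int):
        return size, size
    rows, cols = size
    return int(rows), int(cols)


def gen_bars_stripes(
    size: Union[int, tuple[int, int]],
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    exhaustive: bool = False,
) -> ImageSet:
    """Bars-and-stripes patterns: every row constant, or every column constant.

    Exhaustive mode enumerates all 2^rows row patterns and 2^cols column
    patterns and removes the all-on/all-off duplicates, yielding
    2^rows + 2^cols − 2 unique patterns (2^(size+1) − 2 on a square
    grid). Sampling mode draws n patterns i.i.d. (orientation coin, then
    random on/off bits), reproducibly for a seeded rng.
    """
    rows, cols = _as_rows_cols(size)
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    if exhaustive:
        pats = []
        for bits in range(2**rows):
            on = ((bits >> np.arange(rows)) & 1).astype(np.float64)
            pats.append(np.repeat(on[:, None], cols, axis=1))
        for bits in range(2**cols):
            on = ((bits >> np.arange(cols)) & 1).astype(np.float64)
            pats.append(np.repeat(on[None, :], rows, axis=0))
        flat = np.array([p.ravel() for p in pats], dtype=np.float64)
        flat = np.unique(flat, axis=0)
        return ImageSet(images=flat, height=rows, width=cols)
    if n is None or rng is None:
        raise ValueError("sampling mode requires n and a seeded rng")
    out = np.empty((n, rows * cols), dtype=np.float64)
    for i in range(n):
        if rng.random() < 0.5:
            bits = rng.integers(0, 2, size=rows)
            out[i] = np.repeat(bits[:, None], cols, axis=1).ravel()
        else:
            bits = rng.integers(0, 2, size=cols)
            out[i] = np.repeat(bits[None, :], rows, axis=0).ravel()
    return ImageSet(images=out, height=rows, width=cols)


def gen_prototype_digits(
    n: int,
    n_classes: int = 10,
    size: int = 16,
    flip_prob: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    return_prototypes: bool = False,
):
    """Prototype-plus-noise classes: a desk-scale digit-image stand-in.

    One fixed random binary prototype per class (drawn first from the
    rng, so it is a pure function of the seed), then each sample is its
    class prototype with i.i.d. pixel flips at ``flip_prob``. Classes are
    balanced to within one sample and the presentation order shuffled.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    d = size * size
    prototypes = (rng.random((n_classes, d)) < 0.5).astype(np.float64)
    labels = np.arange(n) % n_classes
    labels = labels[rng.permutation(n)]
    flips = rng.random((n, d)) < flip_prob
    images = np.abs(prototypes[labels] - flips)  # XOR with the flip mask
    out = ImageSet(images=images, height=size, width=size, labels=labels)
    if return_prototypes:
        return out, prototypes
    return out


def gen_dot_images(
    n: int,
    numerosity_range: tuple[int, int] = (1, 8),
    size: int = 32,
    dot_radius_range: tuple[float, float] = (2.0, 4.0),
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 200,
) -> ImageSet:
    """Images of N non-overlapping dots, labeled by their numerosity.

    Each image draws a numerosity uniformly from the inclusive range,
    then places filled discs with random centers and radii so that discs
    never touch (≥1 px gap, so connected components equal the label). An
    infeasible packing raises after bounded retries.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    lo, hi = int(numerosity_range[0]), int(numerosity_range[1])
    if lo < 0 or hi < lo:
        raise ValueError("invalid numerosity range")
    r_lo, r_hi = dot_radius_range
    yy, xx = np.mgrid[0:size, 0:size]
    images = np.zeros((n, size * size), dtype=np.float64)
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        count = int(rng.integers(lo, hi + 1))
        labels[i] = count
        for attempt in range(max_retries):
            centers: list[tuple[float, float, float]] = []
            ok = True
            for _ in range(count):
                placed = False
                for _ in range(max_retries):
                    r = float(rng.uniform(r_lo, r_hi))
                    cx = float(rng.uniform(r + 1, size - r - 1))
                    cy = float(rng.uniform(r + 1, size - r - 1))
                    if all(
                        np.hypot(cx - ox, cy - oy) > r + orad + 1.5
                        for ox, oy, orad in centers
                    ):
                        centers.append((cx, cy, r))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok:
                break
        else:
            raise ValueError(
                f"could not place {count} non-overlapping dots of radius "
                f"[{r_lo}, {r_hi}] on a {size}x{size} grid after {max_retries} retries"
            )
        grid = np.zeros((size, size), dtype=np.float64)
        for cx, cy, r in centers:
            grid[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = 1.0
        images[i] = grid.ravel()
    return ImageSet(images=images, height=size, width=size, labels=labels)
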