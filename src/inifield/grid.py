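"""Intensity normalization and normalized coordinate grids.

Training fits the network in a fixed intensity range (0..100 by default)
against coordinates normalized per axis to [-1, 1]: index ``i`` on an axis
of extent ``n >= 2`` maps to ``-1 + 2 i / (n - 1)``; a degenerate axis of
extent 1 maps to the midpoint 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import DTYPE_CODES, ImageTensor

GRID_DTYPE = np.float32


@dataclass
class NormalizationParams:
    """Affine intensity map ``v' = dst_lo + (v - src_min) * scale``."""

    src_min: float
    src_max: float
    dst_lo: float = 0.0
    dst_hi: float = 100.0

    def __post_init__(self):
        if not self.src_max >= self.src_min:
            raise ValueError("src_max must be >= src_min")
        if not self.dst_hi > self.dst_lo:
            raise ValueError("dst_hi must be > dst_lo")

    @property
    def scale(self) -> float:
        # constant image: degenerate map, everything lands on dst_lo
        if self.src_max == self.src_min:
            return 1.0
        return (self.dst_hi - self.dst_lo) / (self.src_max - self.src_min)

    def to_dict(self) -> dict:
        return {
            "src_min": float(self.src_min),
            "src_max": float(self.src_max),
            "dst_lo": float(self.dst_lo),
            "dst_hi": float(self.dst_hi),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(d["src_min"], d["src_max"], d["dst_lo"], d["dst_hi"])


def minmax_normalize(
    img: ImageTensor, lo: float = 0.0, hi: float = 100.0
) -> tuple[ImageTensor, NormalizationParams]:
    """Map pixel values linearly onto [lo, hi] using the observed min/max.

    Returns the normalized image (float64) and the parameters needed to
    invert the map. Constant images map everywhere to ``lo``.
    """
    if hi <= lo:
        raise ValueError("hi must be > lo")
    x = np.asarray(img.data, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    src_min, src_max = float(x.min()), float(x.max())
    params = NormalizationParams(src_min, src_max, lo, hi)
    out = lo + (x - src_min) * params.scale
    return ImageTensor(out, img.axes), params


def denormalize(
    img_norm: ImageTensor, params: NormalizationParams, dtype_code: str
) -> ImageTensor:
    """Invert the affine map, clip to the target dtype range and round.

    Integer targets use round-half-to-even; float targets are cast.
    """
    if dtype_code not in DTYPE_CODES:
        raise ValueError(f"unknown dtype_code {dtype_code!r}")
    x = np.asarray(img_norm.data, dtype=np.float64)
    v = params.src_min + (x - params.dst_lo) / params.scale
    dt = DTYPE_CODES[dtype_code]
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        v = np.clip(np.rint(v), info.min, info.max)
    return ImageTensor(v.astype(dt), img_norm.axes)


def axis_coords(n: int, dtype=GRID_DTYPE) -> np.ndarray:
    """Normalized coordinates of one axis of extent ``n``."""
    if n < 1:
        raise ValueError("axis extent must be >= 1")
    if n == 1:
        return np.zeros(1, dtype=dtype)
    return (-1.0 + 2.0 * np.arange(n) / (n - 1)).astype(dtype)


@dataclass
class CoordinateGrid:
    """Flattened per-pixel coordinates in row-major canonical order."""

    coords: np.ndarray  # (N_points, D)
    source_shape: tuple

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def multi_index(self, flat: int) -> tuple:
        """Bijection grid row -> multi-index."""
        return tuple(int(v) for v in np.unravel_index(flat, self.source_shape))


def make_grid(shape) -> CoordinateGrid:
    """Build the full normalized coordinate grid for an image shape."""
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("all extents must be >= 1")
    axes = [axis_coords(n) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel(order="C") for m in mesh], axis=1)
    return CoordinateGrid(coords, shape)


def coords_for_indices(shape, multi_indices) -> np.ndarray:
    """Coordinates of an explicit list of multi-indices.

    Bit-identical to the corresponding rows of :func:`make_grid` because
    it evaluates the same per-axis lookup tables.
    """
    shape = tuple(int(s) for s in shape)
    idx = np.asarray(multi_indices)
    if idx.ndim == 1:
        idx = idx[None, :]
    if idx.shape[1] != len(shape):
        raise ValueError("index rank does not match shape rank")
    if idx.size and (idx.min() < 0 or np.any(idx >= np.array(shape))):
        raise IndexError("index out of bounds")
    tables = [axis_coords(n) for n in shape]
    cols = [tables[d][idx[:, d]] for d in range(len(shape))]
    return np.stack(cols, axis=1) if cols else np.zeros((0, 0), dtype=GRID_DTYPE)
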