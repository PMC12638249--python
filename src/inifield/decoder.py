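"""Pixel-addressable decompression.

Because the stored representation is a pure function of coordinates, any
subset of pixels can be decoded by evaluating the network only at the
requested grid points: full volumes, single slices, strided low-resolution
previews, explicit index lists or mask-defined (possibly disconnected)
ROIs. Every partial decode agrees bit-exactly with the corresponding
selection from a full decode, since both evaluate the same function at
the same coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import NormalizationParams, coords_for_indices
from .image import DTYPE_CODES, ImageTensor
from .inif_format import InifFile
from . import backbone

#: evaluation chunk: an internal tunable that must not change outputs
EVAL_CHUNK = 65536


@dataclass
class ROISpec:
    """A decode request."""

    mode: str  # full | slice | stride | indices | mask
    axis: str | None = None
    index: int | None = None
    strides: dict | None = None  # axis label -> stride
    indices: np.ndarray | None = None
    mask: np.ndarray | None = None

    @classmethod
    def full(cls):
        return cls("full")

    @classmethod
    def slice_(cls, axis: str, index: int):
        return cls("slice", axis=axis, index=index)

    @classmethod
    def stride(cls, **strides):
        return cls("stride", strides=strides)

    @classmethod
    def at_indices(cls, indices):
        return cls("indices", indices=np.asarray(indices))

    @classmethod
    def from_mask(cls, mask):
        return cls("mask", mask=np.asarray(mask, dtype=bool))


def _evaluate(model, coords: np.ndarray) -> np.ndarray:
    out = np.empty(coords.shape[0], dtype=model.dtype)
    for i in range(0, coords.shape[0], EVAL_CHUNK):
        out[i : i + EVAL_CHUNK] = backbone.forward(
            model, coords[i : i + EVAL_CHUNK]
        )[:, 0]
    return out


def _finalize(values: np.ndarray, header: dict) -> np.ndarray:
    """Clip in normalized space, invert the affine map, cast to dtype."""
    p = NormalizationParams.from_dict(header["norm"])
    v = np.clip(values.astype(np.float64), p.dst_lo, p.dst_hi)
    v = p.src_min + (v - p.dst_lo) / p.scale
    dt = DTYPE_CODES[header["dtype_code"]]
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        v = np.clip(np.rint(v), info.min, info.max)
    return v.astype(dt)


def _index_grid(per_axis_indices) -> np.ndarray:
    mesh = np.meshgrid(*per_axis_indices, indexing="ij")
    return np.stack([m.ravel(order="C") for m in mesh], axis=1)


def decode(file: InifFile, roi: ROISpec | None = None):
    """Decode a region of interest from a stored model.

    Returns an :class:`ImageTensor` for full/slice/stride requests
    (a slice keeps its axis at extent 1; a stride of s on extent n gives
    ceil(n/s) anchored at index 0), or ``(values, indices)`` for
    indices/mask requests.
    """
    roi = roi or ROISpec.full()
    header = file.header
    shape = tuple(header["shape"])
    axes = header["axes"]
    model = file.model()

    if roi.mode == "full":
        per_axis = [np.arange(n) for n in shape]
        idx = _index_grid(per_axis)
        vals = _finalize(_evaluate(model, coords_for_indices(shape, idx)), header)
        return ImageTensor(vals.reshape(shape), axes)

    if roi.mode == "slice":
        ax = axes.index(roi.axis) if isinstance(roi.axis, str) else int(roi.axis)
        if not 0 <= roi.index < shape[ax]:
            raise IndexError(f"slice index {roi.index} out of range on axis {roi.axis}")
        per_axis = [
            np.array([roi.index]) if d == ax else np.arange(n)
            for d, n in enumerate(shape)
        ]
        idx = _index_grid(per_axis)
        out_shape = tuple(1 if d == ax else n for d, n in enumerate(shape))
        vals = _finalize(_evaluate(model, coords_for_indices(shape, idx)), header)
        return ImageTensor(vals.reshape(out_shape), axes)

    if roi.mode == "stride":
        strides = dict(roi.strides or {})
        per_axis = []
        for d, n in enumerate(shape):
            s = int(strides.pop(axes[d], 1))
            if s < 1:
                raise ValueError("stride must be >= 1")
            per_axis.append(np.arange(0, n, s))
        if strides:
            raise ValueError(f"unknown stride axes {sorted(strides)}")
        idx = _index_grid(per_axis)
        out_shape = tuple(len(a) for a in per_axis)
        vals = _finalize(_evaluate(model, coords_for_indices(shape, idx)), header)
        return ImageTensor(vals.reshape(out_shape), axes)

    if roi.mode == "indices":
        idx = np.asarray(roi.indices)
        vals = _finalize(_evaluate(model, coords_for_indices(shape, idx)), header)
        return vals, idx

    if roi.mode == "mask":
        return decode_mask(file, roi.mask)

    raise ValueError(f"unknown ROI mode {roi.mode!r}")


def decode_mask(file: InifFile, mask):
    """Decode only where the boolean mask is true.

    Returns ``(values, multi_indices)``; equals the masked selection of a
    full decode exactly.
    """
    header = file.header
    shape = tuple(header["shape"])
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match stored {shape}")
    idx = np.argwhere(mask)
    if idx.size == 0:
        dt = DTYPE_CODES[header["dtype_code"]]
        return np.zeros(0, dtype=dt), idx
    model = file.model()
    vals = _finalize(_evaluate(model, coords_for_indices(shape, idx)), header)
    return vals, idx
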