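"""Labeled N-D image container and TIFF input/output.

Microscopy images carry up to five axes — T (time), C (channel), Z (depth),
Y, X — and the whole pipeline assumes a canonical axis order so that
coordinate grids, serialized shapes and decoded arrays always line up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

CANONICAL_AXES = "TCZYX"

#: storage codes understood by the container format
DTYPE_CODES = {"u8": np.uint8, "u16": np.uint16, "f32": np.float32}
DTYPE_BYTES = {"u8": 1, "u16": 2, "f32": 4}


def dtype_code_of(dtype) -> str:
    """Map a numpy dtype to the storage code used in metadata."""
    dt = np.dtype(dtype)
    if dt == np.uint8:
        return "u8"
    if dt == np.uint16:
        return "u16"
    if dt.kind == "f":
        return "f32"
    raise ValueError(f"unsupported image dtype: {dt}")


@dataclass
class ImageTensor:
    """An N-D pixel array with labeled axes.

    Parameters
    ----------
    data : ndarray
        Pixel values; rank must equal ``len(axes)``.
    axes : str
        Axis labels, a subset of ``"TCZYX"`` in canonical order
        (absent axes omitted), e.g. ``"ZYX"`` for a volume.
    """

    data: np.ndarray
    axes: str

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"rank {self.data.ndim} does not match axes {self.axes!r}"
            )
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axis labels in {self.axes!r}")
        if any(a not in CANONICAL_AXES for a in self.axes):
            raise ValueError(f"unknown axis label in {self.axes!r}")
        order = [CANONICAL_AXES.index(a) for a in self.axes]
        if order != sorted(order):
            raise ValueError(
                f"axes {self.axes!r} not in canonical T,C,Z,Y,X order"
            )
        if self.data.size == 0:
            raise ValueError("empty image")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def dtype_code(self) -> str:
        return dtype_code_of(self.data.dtype)

    @property
    def raw_bytes(self) -> int:
        """Uncompressed pixel payload in bytes (extents x dtype bytes)."""
        return int(np.prod(self.shape)) * DTYPE_BYTES[self.dtype_code]

    def axis_index(self, label: str) -> int:
        if label not in self.axes:
            raise ValueError(f"axis {label!r} not present in {self.axes!r}")
        return self.axes.index(label)


def default_axes(rank: int) -> str:
    """Canonical axis guess for an unlabeled array of the given rank."""
    if not 1 <= rank <= 5:
        raise ValueError(f"rank {rank} outside the supported 1..5")
    return CANONICAL_AXES[-rank:]


def canonicalize(data: np.ndarray, axes: str) -> ImageTensor:
    """Reorder arbitrary-order axes into canonical T,C,Z,Y,X order."""
    axes = axes.upper().replace("S", "C")
    if data.ndim != len(axes):
        raise ValueError(f"rank {data.ndim} does not match axes {axes!r}")
    order = sorted(range(len(axes)), key=lambda i: CANONICAL_AXES.index(axes[i]))
    return ImageTensor(np.transpose(data, order), "".join(axes[i] for i in order))


def read_tiff(path, axes_hint: str | None = None) -> ImageTensor:
    """Read a TIFF/OME-TIFF preserving dtype; axes from metadata or hint."""
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = axes_hint or series.axes
    axes = axes.upper().replace("S", "C")
    if any(a not in CANONICAL_AXES for a in axes) or len(axes) != data.ndim:
        if axes_hint is None:
            axes = default_axes(data.ndim)
        else:
            raise ValueError(f"axes hint {axes_hint!r} invalid for rank {data.ndim}")
    return canonicalize(data, axes)


def write_tiff(img: ImageTensor, path) -> None:
    tifffile.imwrite(path, img.data, metadata={"axes": img.axes})
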