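"""Budget planning: turn a target compression ratio into an architecture.

The contract is one-sided: the serialized file — header, metadata and
weights included — must be no larger than ``raw_bytes / target_cr``, so
the achieved ratio is always at least the requested one. The planner
picks the largest width whose exact serialized size fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import parameter_count_for
from .image import DTYPE_BYTES, default_axes
from .inif_format import header_overhead

DEFAULT_DEPTH = 7
MAX_WIDTH = 65536


class InfeasibleBudgetError(ValueError):
    def __init__(self, msg, minimal_cr=None):
        super().__init__(msg)
        self.minimal_cr = minimal_cr


@dataclass
class BudgetPlan:
    raw_bytes: int
    target_cr: float
    header_bytes: int
    bytes_per_param: int
    chosen_width: int
    depth: int
    achieved_cr: float  # planning estimate; final value comes from the file

    @property
    def file_bytes(self) -> int:
        return int(round(self.raw_bytes / self.achieved_cr))


def compression_ratio(raw_bytes: int, file_bytes: int) -> float:
    """Uncompressed pixel bytes divided by compressed file bytes."""
    if file_bytes <= 0:
        raise ValueError("file_bytes must be > 0")
    return raw_bytes / file_bytes


def _default_metadata(shape, dtype_code, depth, bytes_per_param):
    return {
        "axes": default_axes(len(shape)),
        "shape": [int(s) for s in shape],
        "dtype_code": dtype_code,
        "weight_dtype": "f16" if bytes_per_param == 2 else "f32",
        "norm": {"src_min": 0.0, "src_max": 65535.0, "dst_lo": 0.0, "dst_hi": 100.0},
        "arch": {
            "depth": depth, "width": 1, "in_dim": len(shape),
            "out_dim": 1, "omega0": 30.0,
        },
        "seed": 0,
        "guidance": None,
        "hybrid": None,
    }


def serialized_size(
    width: int, metadata: dict, bytes_per_param: int
) -> int:
    """Exact on-disk size of an INIF file with the given width."""
    meta = dict(metadata)
    arch = dict(meta["arch"])
    arch["width"] = int(width)
    meta["arch"] = arch
    n = parameter_count_for(
        arch["in_dim"], arch["out_dim"], width, arch["depth"]
    )
    return header_overhead(meta) + n * bytes_per_param


def plan_architecture(
    shape,
    dtype_code: str,
    target_cr: float,
    depth: int = DEFAULT_DEPTH,
    bytes_per_param: int = 4,
    metadata: dict | None = None,
    extra_payload: int = 0,
) -> BudgetPlan:
    """Largest width whose serialized size fits floor(raw_bytes/target_cr).

    ``metadata`` may be the real header dict (so the header length is exact);
    ``extra_payload`` reserves bytes for e.g. a hybrid codec payload.
    """
    if target_cr <= 1:
        raise ValueError("target_cr must be > 1")
    shape = tuple(int(s) for s in shape)
    raw = int(np.prod(shape)) * DTYPE_BYTES[dtype_code]
    budget = int(raw / target_cr)
    meta = metadata if metadata is not None else _default_metadata(
        shape, dtype_code, depth, bytes_per_param
    )

    def size(w):
        return serialized_size(w, meta, bytes_per_param) + extra_payload

    if size(1) > budget:
        min_cr = raw / size(1)
        raise InfeasibleBudgetError(
            f"target CR {target_cr} infeasible; minimal feasible CR is "
            f"about {min_cr:.1f}",
            minimal_cr=min_cr,
        )
    lo, hi = 1, 2
    while hi <= MAX_WIDTH and size(hi) <= budget:
        lo, hi = hi, hi * 2
    hi = min(hi, MAX_WIDTH)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if size(mid) <= budget:
            lo = mid
        else:
            hi = mid - 1
    # header length is only piecewise-monotone in the width's digit count;
    # fix up locally so the result is exactly the largest feasible width
    w = lo
    while w > 1 and size(w) > budget:
        w -= 1
    while w < MAX_WIDTH and size(w + 1) <= budget:
        w += 1
    return BudgetPlan(
        raw_bytes=raw,
        target_cr=float(target_cr),
        header_bytes=header_overhead({**meta, "arch": {**meta["arch"], "width": w}}) - 8,
        bytes_per_param=bytes_per_param,
        chosen_width=w,
        depth=depth,
        achieved_cr=raw / size(w),
    )
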