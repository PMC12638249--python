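"""Reconstruction-quality and ratio metrics: PSNR, SSIM, CR.

Metrics are computed in source-dtype units with ``data_range`` equal to
the dtype maximum (255 for u8, 65535 for u16) unless overridden. SSIM
uses the standard Gaussian 11x11 window (sigma 1.5, k1=0.01, k2=0.03);
for stacks of more than two dimensions it is averaged over 2-D Y-X
planes.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .image import ImageTensor
from .sizing import compression_ratio  # re-exported convenience

__all__ = ["psnr", "ssim", "compression_ratio", "default_data_range"]

_DTYPE_RANGE = {"u8": 255.0, "u16": 65535.0, "f32": 1.0}


def default_data_range(dtype_code: str) -> float:
    return _DTYPE_RANGE[dtype_code]


def _pair(a, b):
    a = a.data if isinstance(a, ImageTensor) else np.asarray(a)
    b = b.data if isinstance(b, ImageTensor) else np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.astype(np.float64), b.astype(np.float64)


def psnr(a, b, data_range: float) -> float:
    """10 log10(range^2 / MSE); identical inputs give +inf."""
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    a, b = _pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(
    a,
    b,
    data_range: float,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity; per-Y-X-plane mean for >2-D inputs."""
    a, b = _pair(a, b)
    if a.ndim < 2:
        raise ValueError("ssim needs at least 2 dimensions")
    if min(a.shape[-2:]) < window:
        raise ValueError(
            f"image planes {a.shape[-2:]} smaller than the {window}x{window} window"
        )

    def plane(x, y):
        return structural_similarity(
            x, y,
            win_size=window, gaussian_weights=True, sigma=1.5,
            K1=k1, K2=k2, data_range=data_range,
            use_sample_covariance=False,
        )

    if a.ndim == 2:
        return float(plane(a, b))
    lead = a.reshape(-1, *a.shape[-2:])
    lead_b = b.reshape(-1, *b.shape[-2:])
    return float(np.mean([plane(x, y) for x, y in zip(lead, lead_b)]))
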