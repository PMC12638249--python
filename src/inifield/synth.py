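"""Seeded synthetic microscopy images for testing and benchmarking.

The generators emulate the image families the compressor is aimed at:
DNA-stained nucleus volumes (bright textured ellipsoids), filamentous
proteins with periodic striped intensity, multiplexed multichannel fields
with tunable colocalization, and Poisson-Gaussian shot/read noise as
produced by low-laser-power live imaging. Every generator is a pure
function of its arguments and seed. They are deliberately simple optical
models: no PSF, no depth attenuation, no chromatic registration errors.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import DTYPE_CODES, ImageTensor

_FOREGROUND = 30000.0
_BACKGROUND = 600.0


def _bandlimited_noise(rng, shape, sigma):
    n = gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return n / s if s > 0 else n


def make_nuclei_volume(
    shape=(24, 48, 48),
    n_nuclei: int = 4,
    texture_amp: float = 0.3,
    seed: int = 0,
) -> ImageTensor:
    """3-D volume (Z, Y, X) of ellipsoidal nucleus-like bodies with smooth
    internal texture on a dim background, uint16."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("nuclei volume must be 3D (Z, Y, X)")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vol = np.zeros(shape, dtype=np.float64)

    radii_base = np.array([max(s / 7.0, 1.5) for s in shape])
    # 1.2 is the upper size jitter below; a nucleus must fit with margin
    if n_nuclei > 0 and np.any(2 * 1.2 * radii_base > np.array(shape)):
        raise ValueError("nuclei larger than volume")
    placed = []
    attempts = 0
    while len(placed) < n_nuclei and attempts < 2000:
        attempts += 1
        r = radii_base * rng.uniform(0.8, 1.2, size=3)
        c = np.array([rng.uniform(rad, s - rad) for rad, s in zip(r, shape)])
        if all(np.linalg.norm((c - pc) / (r + pr)) > 1.1 for pc, pr in placed):
            placed.append((c, r))
    if len(placed) < n_nuclei:
        raise ValueError("could not place non-overlapping nuclei in this volume")

    for c, r in placed:
        d2 = (
            ((zz - c[0]) / r[0]) ** 2
            + ((yy - c[1]) / r[1]) ** 2
            + ((xx - c[2]) / r[2]) ** 2
        )
        body = np.clip(1.0 - d2, 0.0, 1.0) ** 0.5
        vol = np.maximum(vol, body)

    texture = 1.0 + texture_amp * _bandlimited_noise(rng, shape, sigma=2.0)
    img = _BACKGROUND + vol * _FOREGROUND * np.clip(texture, 0.0, None)
    img += 30.0 * _bandlimited_noise(rng, shape, sigma=1.0)
    return ImageTensor(np.clip(img, 0, 65535).astype(np.uint16), "ZYX")


def make_filament_image(
    shape=(96, 96),
    n_fibers: int = 4,
    stripe_period: float = 8.0,
    seed: int = 0,
) -> ImageTensor:
    """Curvilinear fibers with periodic intensity modulation along their
    arc length (period in pixels), 2-D (Y, X) or 3-D (Z, Y, X) uint16."""
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3):
        raise ValueError("filament image must be 2D or 3D")
    if stripe_period < 2:
        raise ValueError("stripe period must be >= 2 px")
    rng = np.random.default_rng(seed)
    is3d = len(shape) == 3
    plane_shape = shape[-2:]
    acc = np.zeros(shape, dtype=np.float64)

    for _ in range(n_fibers):
        h, w = plane_shape
        pos = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        theta = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(0, shape[0] - 1) if is3d else None
        step = 0.5
        length = rng.uniform(0.8, 1.4) * max(plane_shape)
        s = 0.0
        while s < length:
            theta += rng.normal(0, 0.03)
            pos = pos + step * np.array([np.sin(theta), np.cos(theta)])
            s += step
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            # striped modulation along the fiber
            inten = 0.15 + 0.85 * 0.5 * (1 + np.cos(2 * np.pi * s / stripe_period))
            iy, ix = int(pos[0]), int(pos[1])
            if is3d:
                acc[int(round(z)), iy, ix] += inten
            else:
                acc[iy, ix] += inten

    acc = gaussian_filter(acc, sigma=(0.0, 0.7, 0.7) if is3d else 0.7)
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    img = _BACKGROUND + acc * _FOREGROUND
    img += 20.0 * _bandlimited_noise(rng, shape, sigma=1.0)
    axes = "ZYX" if is3d else "YX"
    return ImageTensor(np.clip(img, 0, 65535).astype(np.uint16), axes)


def _structure_map(rng, shape):
    field = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    field -= field.mean()
    s = field.std()
    if s > 0:
        field /= s
    return np.clip(field, 0, None) ** 1.5


def make_multichannel(
    shape=(96, 96),
    n_channels: int = 3,
    colocalization: float = 0.5,
    seed: int = 0,
) -> ImageTensor:
    """Multichannel image with a shared base structure: each channel past
    the first mixes a fresh structure with channel 0 at the given weight,
    so inter-channel Pearson correlation grows with the weight."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0 <= colocalization <= 1:
        raise ValueError("colocalization must be in [0, 1]")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    base = _structure_map(rng, shape)
    chans = [base]
    for _ in range(1, n_channels):
        fresh = _structure_map(rng, shape)
        chans.append(colocalization * base + (1 - colocalization) * fresh)
    stack = np.stack(chans, axis=0)
    peak = stack.max()
    if peak > 0:
        stack = stack / peak
    img = _BACKGROUND + stack * _FOREGROUND
    axes = "C" + ("ZYX" if len(shape) == 3 else "YX")
    return ImageTensor(np.clip(img, 0, 65535).astype(np.uint16), axes)


def add_low_laser_noise(
    img: ImageTensor,
    photon_scale: float = 100.0,
    read_sigma: float = 200.0,
    seed: int = 0,
) -> ImageTensor:
    """Poisson shot noise (``photon_scale`` expected photons at full
    intensity) plus Gaussian read noise (in intensity units), clipped to
    the source dtype. Lower photon counts mean lower PSNR vs the clean
    input — the low-laser-power regime."""
    if photon_scale <= 0:
        raise ValueError("photon_scale must be > 0")
    rng = np.random.default_rng(seed)
    dt = DTYPE_CODES[img.dtype_code]
    full = float(np.iinfo(dt).max) if np.issubdtype(dt, np.integer) else 1.0
    x01 = img.data.astype(np.float64) / full
    photons = rng.poisson(np.clip(x01, 0, None) * photon_scale)
    noisy01 = photons / photon_scale
    out = noisy01 * full + rng.normal(0.0, read_sigma, size=img.shape)
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        out = np.clip(np.rint(out), info.min, info.max)
    return ImageTensor(out.astype(dt), img.axes)
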