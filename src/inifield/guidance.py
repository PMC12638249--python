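"""Application-specific guidance losses.

Two guidance terms can be added to the per-pixel similarity loss during
compression:

* **Segmentation guidance** — penalizes 1 minus the intersection-over-union
  between segmentations of the original and the decoded image, so that
  structures relevant to downstream analysis survive compression. The
  evaluation segmenter (``reference_segment``) is a deterministic
  filament-segmentation pipeline (auto-contrast, edge-preserving Gaussian
  smoothing, ridge filtering, small-object removal). Because it is not
  differentiable, training uses a smooth surrogate (``soft_segment`` +
  soft IoU) whose hard-threshold limit recovers the reference behaviour.

* **Perceptual guidance** — a layer-weighted squared distance between
  feature maps of a decoded patch and a patch from clean reference data,
  used to suppress noise when compressing low-laser-power acquisitions.
  The default feature extractor is a small fixed, seeded convolutional
  stack; any pretrained network exposing the same interface can be
  substituted.

All losses are non-negative and zero at identity; gradients with respect
to the decoded pixels are analytic and finite-difference checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter, gaussian_laplace
from scipy.ndimage import label as cc_label
from skimage.filters import sato
from skimage.morphology import skeletonize

from .image import ImageTensor

_FILT_MODE = "constant"  # zero-padded correlation: self-adjoint for symmetric kernels


# ---------------------------------------------------------------------------
# configs


@dataclass
class SegParams:
    """Filament-segmentation parameters (defaults follow the reference
    pipeline: contrast bounds [1.5, 10.5] in units of the intensity
    standard deviation, smoothing sigma 1, ridge scale/cutoff [1, 0.01],
    objects below 20 px removed)."""

    contrast_bounds: tuple = (1.5, 10.5)
    smoothing_sigma: float = 1.0
    filament_scales: tuple = (1.0, 0.01)
    min_object_size: int = 20
    soft_threshold_temp: float = 0.02

    def __post_init__(self):
        if self.min_object_size < 0:
            raise ValueError("min_object_size must be >= 0")


@dataclass
class PercParams:
    patch_size: int = 32
    layer_weights: list | None = None
    feature_net_id: str = "toyconv"
    feature_net_seed: int = 0


@dataclass
class GuidanceConfig:
    mode: str = "none"  # none | segmentation | perceptual
    weight: float = 0.0
    seg_params: SegParams = field(default_factory=SegParams)
    perc_params: PercParams = field(default_factory=PercParams)
    apply_every: int = 1
    reference: object = None  # clean reference image for perceptual mode
    seg_target: str = "reference"  # trainer target: reference | soft
    #: balance factor putting the dimensionless guidance losses on the
    #: squared-intensity scale of the similarity term
    balance: float = 1000.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("guidance weight must be >= 0")
        if self.mode not in ("none", "segmentation", "perceptual"):
            raise ValueError(f"unknown guidance mode {self.mode!r}")

    def summary(self) -> dict | None:
        if self.mode == "none" or self.weight == 0:
            return None
        return {"mode": self.mode, "weight": float(self.weight)}


# ---------------------------------------------------------------------------
# IoU


def _as_mask(m) -> np.ndarray:
    m = m.data if isinstance(m, ImageTensor) else np.asarray(m)
    m = m.astype(np.float64)
    if m.size and (m.min() < 0 or m.max() > 1):
        raise ValueError("mask values must lie in [0, 1]")
    return m


def iou(mask_a, mask_b) -> float:
    """Intersection over union. Works for binary and soft masks
    (``sum(a*b) / sum(a + b - a*b)``); two empty masks agree perfectly
    and give 1."""
    a, b = _as_mask(mask_a), _as_mask(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = float(np.sum(a * b))
    union = float(np.sum(a + b - a * b))
    if union == 0.0:
        return 1.0
    return inter / union


def _soft_iou_grad(a: np.ndarray, b: np.ndarray):
    """(soft Jaccard, d/d a): sum(min)/sum(max).

    This soft IoU equals 1 exactly when a == b (so the segmentation loss
    vanishes at identity), coincides with the product form
    ``sum(ab)/sum(a+b-ab)`` whenever b is binary, and is differentiable
    almost everywhere.
    """
    inter = float(np.sum(np.minimum(a, b)))
    union = float(np.sum(np.maximum(a, b)))
    if union == 0.0:
        return 1.0, np.zeros_like(a)
    grad = ((a < b) * union - inter * (a > b)) / union**2
    return inter / union, grad


# ---------------------------------------------------------------------------
# reference (evaluation) segmenter


def _auto_contrast(x: np.ndarray, bounds) -> np.ndarray:
    """Clip to [mean - k_lo*std, mean + k_hi*std] and rescale to [0, 1]."""
    k_lo, k_hi = bounds
    mu, sd = float(x.mean()), float(x.std())
    lo = max(mu - k_lo * sd, float(x.min()))
    hi = min(mu + k_hi * sd, float(x.max()))
    if hi <= lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def reference_segment(img, p: SegParams = SegParams()) -> np.ndarray:
    """Deterministic filament segmentation used for evaluation.

    Pipeline: auto-contrast normalization -> Gaussian smoothing ->
    ridge (filament) response at the configured scale, thresholded at the
    configured cutoff -> removal of connected components smaller than
    ``min_object_size``. Returns a boolean mask.
    """
    x = img.data if isinstance(img, ImageTensor) else np.asarray(img)
    x = np.squeeze(np.asarray(x, dtype=np.float64))
    if x.ndim not in (2, 3):
        raise ValueError("reference_segment expects a 2D or 3D single-channel image")
    x = _auto_contrast(x, p.contrast_bounds)
    if x.max() == 0:
        return np.zeros(x.shape, dtype=bool)
    x = gaussian_filter(x, p.smoothing_sigma)
    scale, cutoff = p.filament_scales
    resp = sato(x, sigmas=[scale], black_ridges=False)
    mask = resp > cutoff
    if p.min_object_size > 1:
        mask = _remove_small_filaments(mask, int(p.min_object_size))
    return mask


def _remove_small_filaments(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop components whose centreline (skeleton) length is < min_size.

    Skeleton length is the natural size measure for filamentous objects:
    the thresholded ridge response inflates every object by roughly the
    filter scale, so footprint area would over-count small specks.
    """
    if not mask.any():
        return mask
    lab, n = cc_label(mask)
    skel = skeletonize(mask)
    sizes = np.bincount(lab[skel], minlength=n + 1)
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


# ---------------------------------------------------------------------------
# differentiable surrogate


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _soft_response(x01: np.ndarray, p: SegParams) -> np.ndarray:
    s = gaussian_filter(x01, p.smoothing_sigma, mode=_FILT_MODE)
    scale, _ = p.filament_scales
    # negative Laplacian-of-Gaussian: positive on bright ridges/blobs
    return -gaussian_laplace(s, scale, mode=_FILT_MODE)


def soft_segment(img_norm, p: SegParams, input_range: float = 100.0) -> np.ndarray:
    """Differentiable surrogate segmentation in [0, 1].

    Gaussian smoothing, a negative-LoG ridge response and a sigmoid
    threshold ``sigmoid((r - cutoff)/tau)``; as ``tau -> 0`` it converges
    pointwise (away from the decision boundary) to the hard threshold.
    """
    if p.soft_threshold_temp <= 0:
        raise ValueError("soft_threshold_temp must be > 0")
    x = img_norm.data if isinstance(img_norm, ImageTensor) else np.asarray(img_norm)
    x01 = np.asarray(x, dtype=np.float64) / input_range
    r = _soft_response(x01, p)
    _, cutoff = p.filament_scales
    return _sigmoid((r - cutoff) / p.soft_threshold_temp)


def _soft_segment_vjp(
    img_norm, p: SegParams, d_mask: np.ndarray, input_range: float = 100.0
) -> np.ndarray:
    """Backpropagate d(loss)/d(mask) to d(loss)/d(image)."""
    x = img_norm.data if isinstance(img_norm, ImageTensor) else np.asarray(img_norm)
    x01 = np.asarray(x, dtype=np.float64) / input_range
    r = _soft_response(x01, p)
    _, cutoff = p.filament_scales
    m = _sigmoid((r - cutoff) / p.soft_threshold_temp)
    d_r = d_mask * m * (1.0 - m) / p.soft_threshold_temp
    # adjoint of (-LoG then smoothing): both filters are symmetric and
    # zero-padded, hence self-adjoint
    scale, _ = p.filament_scales
    d_s = -gaussian_laplace(d_r, scale, mode=_FILT_MODE)
    d_x01 = gaussian_filter(d_s, p.smoothing_sigma, mode=_FILT_MODE)
    return d_x01 / input_range


def segmentation_loss(
    decoded_patch, original_patch, p: SegParams = SegParams(),
    target_mode: str = "soft",
) -> float:
    """1 - soft-IoU between the decoded image's surrogate segmentation and
    the original's mask; in [0, 1] and 0 when decoded == original (soft
    target mode)."""
    loss, _ = segmentation_loss_grad(decoded_patch, original_patch, p, target_mode)
    return loss


def segmentation_loss_grad(
    decoded_patch, original_patch, p: SegParams = SegParams(),
    target_mode: str = "soft",
):
    """(loss, d loss / d decoded). The original's mask is a constant target:
    its own soft surrogate (``target_mode="soft"``, zero at identity) or
    the hard reference segmentation (``"reference"``, the trainer's choice
    since it aligns the surrogate with the evaluation segmenter)."""
    dec = decoded_patch.data if isinstance(decoded_patch, ImageTensor) else np.asarray(decoded_patch)
    ori = original_patch.data if isinstance(original_patch, ImageTensor) else np.asarray(original_patch)
    if dec.shape != ori.shape:
        raise ValueError(f"shape mismatch: {dec.shape} vs {ori.shape}")
    if target_mode == "soft":
        target = soft_segment(ori, p)  # stop-gradient
    elif target_mode == "reference":
        target = reference_segment(ori, p).astype(np.float64)
    else:
        raise ValueError(f"unknown target_mode {target_mode!r}")
    m = soft_segment(dec, p)
    val, d_iou_dm = _soft_iou_grad(m, target)
    d_img = _soft_segment_vjp(dec, p, -d_iou_dm)
    return 1.0 - val, d_img


# ---------------------------------------------------------------------------
# perceptual loss


class IdentityFeatureNet:
    """Single-layer identity features: the perceptual loss degenerates to
    mean squared pixel difference."""

    def features(self, x: np.ndarray):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        return [x]

    def features_cached(self, x):
        return self.features(x), None

    def vjp(self, cache, d_feats):
        d = d_feats[0]
        return d[0] if d.shape[0] == 1 else d


class ConvFeatureNet:
    """Small fixed, seeded convolutional stack (tanh nonlinearities).

    Not a pretrained perceptual model — a deterministic stand-in feature
    extractor with the same interface, so that externally supplied
    pretrained networks can be dropped in.
    """

    def __init__(self, seed: int = 0, channels=(4, 8, 8), kernel: int = 3, in_channels: int = 1):
        rng = np.random.default_rng(seed)
        self.kernel = kernel
        self.filters = []
        cin = in_channels
        for cout in channels:
            scale = 1.0 / np.sqrt(kernel * kernel * cin)
            self.filters.append(
                rng.uniform(-scale, scale, size=(cout, cin, kernel, kernel))
            )
            cin = cout

    @property
    def n_layers(self) -> int:
        return len(self.filters)

    @staticmethod
    def _conv_valid(x, f):
        # x (Cin,H,W), f (Cout,Cin,k,k) -> (Cout,H-k+1,W-k+1)
        win = sliding_window_view(x, f.shape[2:], axis=(1, 2))  # (Cin,Ho,Wo,k,k)
        return np.einsum("chwij,ocij->ohw", win, f, optimize=True)

    @staticmethod
    def _conv_valid_adjoint(d_out, f):
        # adjoint of _conv_valid w.r.t. x: full correlation with flipped kernels
        k = f.shape[2]
        pad = np.pad(d_out, ((0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        win = sliding_window_view(pad, (k, k), axis=(1, 2))  # (Cout,H,W,k,k)
        f_fl = f[:, :, ::-1, ::-1]
        return np.einsum("ohwij,ocij->chw", win, f_fl, optimize=True)

    def features_cached(self, x: np.ndarray):
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        feats, cache = [], {"inputs": [], "acts": [], "squeeze": squeeze}
        h = x
        for f in self.filters:
            if h.shape[1] < self.kernel or h.shape[2] < self.kernel:
                raise ValueError("patch smaller than the receptive field")
            cache["inputs"].append(h)
            a = self._conv_valid(h, f)
            t = np.tanh(a)
            cache["acts"].append(t)
            feats.append(t)
            h = t
        return feats, cache

    def features(self, x):
        return self.features_cached(x)[0]

    def vjp(self, cache, d_feats):
        d_h = None
        for l in range(self.n_layers - 1, -1, -1):
            d = d_feats[l].copy() if d_feats[l] is not None else 0.0
            if d_h is not None:
                d = d + d_h
            d_a = d * (1.0 - cache["acts"][l] ** 2)
            d_h = self._conv_valid_adjoint(d_a, self.filters[l])
        return d_h[0] if cache["squeeze"] else d_h


def make_feature_net(p: PercParams):
    if p.feature_net_id == "toyconv":
        return ConvFeatureNet(seed=p.feature_net_seed)
    if p.feature_net_id == "identity":
        return IdentityFeatureNet()
    raise ValueError(f"unknown feature_net_id {p.feature_net_id!r}")


def perceptual_loss(patch_hat, patch_ref, feature_net, w=None) -> float:
    """Layer-weighted feature-map distance.

    ``sum_i 1/(H_i W_i) sum_{h,w} || w_i (Phi_i(hat) - Phi_i(ref)) ||^2``
    where ``Phi_i`` is feature map ``i`` and ``w_i`` scales its channels.
    Zero iff all feature maps agree.
    """
    loss, _ = _perceptual_core(patch_hat, patch_ref, feature_net, w, want_grad=False)
    return loss


def perceptual_loss_grad(patch_hat, patch_ref, feature_net, w=None):
    return _perceptual_core(patch_hat, patch_ref, feature_net, w, want_grad=True)


def _perceptual_core(patch_hat, patch_ref, feature_net, w, want_grad):
    ph = np.asarray(patch_hat, dtype=np.float64)
    pr = np.asarray(patch_ref, dtype=np.float64)
    if ph.shape != pr.shape:
        raise ValueError("patch shapes differ")
    fh, cache = feature_net.features_cached(ph)
    fr = feature_net.features(pr)
    if w is not None and len(w) != len(fh):
        raise ValueError("layer weight count does not match feature layers")
    loss = 0.0
    d_feats = [None] * len(fh)
    for i, (a, b) in enumerate(zip(fh, fr)):
        wi = 1.0 if w is None else np.reshape(np.asarray(w[i], dtype=np.float64), (-1, 1, 1))
        delta = wi * (a - b)
        hw = a.shape[-1] * a.shape[-2]
        loss += float(np.sum(delta**2)) / hw
        if want_grad:
            d_feats[i] = 2.0 * wi * delta / hw
    if not want_grad:
        return loss, None
    return loss, feature_net.vjp(cache, d_feats)


# ---------------------------------------------------------------------------
# patch sampling


def sample_guided_patches(decoded_provider, reference_img, p: PercParams, seed: int):
    """Draw one patch from the reconstruction and one from the clean
    reference, at independent seeded uniform locations.

    ``decoded_provider`` must expose ``shape`` (H, W) and be callable as
    ``provider(y0, x0, patch_size)`` returning the rendered patch (this is
    where gradients flow in the trainer); the reference patch is a plain
    constant array.
    """
    ref = reference_img.data if isinstance(reference_img, ImageTensor) else np.asarray(reference_img)
    ref = np.squeeze(ref)
    ps = p.patch_size
    hh, hw = decoded_provider.shape
    rh, rw = ref.shape[-2], ref.shape[-1]
    if ps > min(hh, hw) or ps > min(rh, rw):
        raise ValueError("patch larger than source")
    rng = np.random.default_rng(seed)
    y0 = int(rng.integers(0, hh - ps + 1))
    x0 = int(rng.integers(0, hw - ps + 1))
    ry = int(rng.integers(0, rh - ps + 1))
    rx = int(rng.integers(0, rw - ps + 1))
    patch_hat = decoded_provider(y0, x0, ps)
    if ref.ndim == 2:
        patch_ref = ref[ry : ry + ps, rx : rx + ps]
    else:
        z = int(rng.integers(0, ref.shape[0]))
        patch_ref = ref[z, ry : ry + ps, rx : rx + ps]
    return patch_hat, patch_ref
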