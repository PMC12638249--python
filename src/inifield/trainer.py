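"""The compression loop: fit the coordinate network to pixel values.

Compression *is* training: a per-image sinusoidal MLP, sized by the byte
budget, is fitted to reproduce the normalized intensities at normalized
grid coordinates under a mean-squared similarity loss, optionally plus
application-specific guidance terms. The fitted weights and the metadata
needed to decode are then serialized into a single INIF file.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import backbone, guidance as gd, optim
from .grid import make_grid, coords_for_indices, minmax_normalize
from .image import ImageTensor
from .inif_format import InifFile, make_file
from .sizing import compression_ratio, plan_architecture

DEFAULT_STEPS = 5000
DEFAULT_BATCH = 65536


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class CompressionConfig:
    target_cr: float = 256.0
    steps: int = DEFAULT_STEPS
    batch_points: int = DEFAULT_BATCH
    seed: int = 0
    optimizer_id: str = "adam"
    optimizer_params: dict = field(default_factory=dict)
    guidance: gd.GuidanceConfig | None = None
    log_every: int = 100
    depth: int = 7
    omega0: float = 30.0
    bytes_per_param: int = 4
    lr: float = 1e-3
    lr_min: float = 1e-5
    dst_lo: float = 0.0
    dst_hi: float = 100.0
    verbose: bool = False

    def __post_init__(self):
        if self.steps < 1 or self.batch_points < 1:
            raise ValueError("steps and batch_points must be >= 1")


def mse_loss(pred, target) -> float:
    """Mean of squared differences."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != target.shape:
        raise ValueError("length mismatch")
    return float(np.mean((pred - target) ** 2))


def _cosine_lr(step: int, total: int, lr0: float, lr_min: float) -> float:
    t = min(step, total) / max(total, 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * t))


def lr_scale_policy(model, cfg) -> list:
    """Per-tensor learning-rate multipliers.

    The hidden sine layers need small steps (their init scale is
    ~sqrt(6/fan_in)/omega0), while the affine output head must traverse
    the full intensity range; scaling the head's rate by the half-range
    keeps both well conditioned under one base rate.
    """
    scales = [1.0] * (2 * len(model.weights) + 1)
    head = 0.5 * (cfg.dst_hi - cfg.dst_lo)
    scales[-3] = head  # output weights
    scales[-2] = head  # output bias
    return scales


def build_metadata(img: ImageTensor, params, cfg: CompressionConfig, width: int) -> dict:
    return {
        "axes": img.axes,
        "shape": [int(s) for s in img.shape],
        "dtype_code": img.dtype_code,
        "weight_dtype": "f16" if cfg.bytes_per_param == 2 else "f32",
        "norm": params.to_dict(),
        "arch": {
            "depth": int(cfg.depth),
            "width": int(width),
            "in_dim": len(img.shape),
            "out_dim": 1,
            "omega0": float(cfg.omega0),
        },
        "seed": int(cfg.seed),
        "target_cr": float(cfg.target_cr),
        "guidance": cfg.guidance.summary() if cfg.guidance else None,
        "hybrid": None,
    }


def _epoch_batches(rng, n, batch):
    """Seeded permutation consumed in batches, reshuffled per epoch."""
    while True:
        perm = rng.permutation(n)
        for i in range(0, n, batch):
            yield perm[i : i + batch]


class _PlaneProvider:
    """Renders Y-X patches from the model on a fixed plane (grad flows)."""

    def __init__(self, model, img_shape, plane_prefix):
        self.model = model
        self.img_shape = tuple(img_shape)
        self.prefix = tuple(plane_prefix)  # leading indices (e.g. a Z index)
        self.shape = tuple(img_shape[-2:])
        self.last_cache = None
        self.last_coords = None

    def __call__(self, y0, x0, ps):
        ys, xs = np.meshgrid(
            np.arange(y0, y0 + ps), np.arange(x0, x0 + ps), indexing="ij"
        )
        lead = np.tile(np.array(self.prefix, dtype=np.int64), (ps * ps, 1))
        idx = np.concatenate(
            [lead, ys.reshape(-1, 1), xs.reshape(-1, 1)], axis=1
        ) if lead.size else np.stack([ys.ravel(), xs.ravel()], axis=1)
        coords = coords_for_indices(self.img_shape, idx)
        y, cache = backbone.forward_cached(self.model, coords)
        self.last_cache = cache
        return y[:, 0].reshape(ps, ps)


def _accumulate(total, extra, weight):
    for t, e in zip(total.param_list(), extra.param_list()):
        t += weight * e.astype(t.dtype)


def compress(img: ImageTensor, cfg: CompressionConfig) -> InifFile:
    """Fit a budgeted coordinate network to the image; returns the INIF unit
    (with the training-loss trace attached as ``loss_trace``)."""
    t_start = time.time()
    normalized, params = minmax_normalize(img, cfg.dst_lo, cfg.dst_hi)
    meta = build_metadata(img, params, cfg, width=1)
    plan = plan_architecture(
        img.shape, img.dtype_code, cfg.target_cr,
        depth=cfg.depth, bytes_per_param=cfg.bytes_per_param, metadata=meta,
    )
    meta["arch"]["width"] = plan.chosen_width

    grid = make_grid(img.shape)
    targets = normalized.data.ravel(order="C").astype(np.float32)[:, None]
    n = grid.n_points

    model = backbone.init_model(
        in_dim=len(img.shape), out_dim=1, width=plan.chosen_width,
        depth=cfg.depth, omega0=cfg.omega0, seed=cfg.seed,
    )
    params_list = model.param_list()
    state = optim.make_state(
        cfg.optimizer_id, params_list, lr=cfg.lr,
        lr_scales=lr_scale_policy(model, cfg), **cfg.optimizer_params,
    )

    rng = np.random.default_rng(cfg.seed + 1)
    batches = _epoch_batches(rng, n, min(cfg.batch_points, n))

    g = cfg.guidance
    guided = g is not None and g.mode != "none" and g.weight > 0
    ref_norm = None
    feature_net = None
    if guided and g.mode == "perceptual":
        if g.reference is None:
            raise ValueError("perceptual guidance requires a reference image")
        ref_img = g.reference if isinstance(g.reference, ImageTensor) else ImageTensor(
            np.asarray(g.reference), img.axes[-np.asarray(g.reference).ndim:]
        )
        ref_norm, _ = minmax_normalize(ref_img, cfg.dst_lo, cfg.dst_hi)
        feature_net = gd.make_feature_net(g.perc_params)

    trace = []
    for step in range(cfg.steps):
        idx = next(batches)
        X = grid.coords[idx]
        t = targets[idx]
        y, cache = backbone.forward_cached(model, X)
        diff = y - t
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        d_out = (2.0 / len(idx)) * diff
        grads = backbone.backward(model, cache, d_out)
        total_loss = loss

        if guided and step % g.apply_every == 0:
            scale = g.weight * g.balance
            if g.mode == "segmentation":
                y_full, cache_full = backbone.forward_cached(model, grid.coords)
                dec = y_full[:, 0].reshape(img.shape)
                g_loss, d_img = gd.segmentation_loss_grad(
                    dec, normalized.data, g.seg_params, target_mode=g.seg_target
                )
                g_grads = backbone.backward(
                    model, cache_full, d_img.reshape(-1, 1)
                )
                _accumulate(grads, g_grads, scale)
                total_loss += scale * g_loss
            else:  # perceptual
                prefix = tuple(
                    int(rng.integers(0, s)) for s in img.shape[:-2]
                )
                provider = _PlaneProvider(model, img.shape, prefix)
                patch_seed = int(rng.integers(0, 2**31 - 1))
                patch_hat, patch_ref = gd.sample_guided_patches(
                    provider, ref_norm, g.perc_params, patch_seed
                )
                # feature nets see patches on a unit scale
                rng_span = cfg.dst_hi - cfg.dst_lo
                g_loss, d_patch = gd.perceptual_loss_grad(
                    patch_hat / rng_span, np.asarray(patch_ref) / rng_span,
                    feature_net, g.perc_params.layer_weights,
                )
                g_grads = backbone.backward(
                    model, provider.last_cache,
                    d_patch.reshape(-1, 1) / rng_span,
                )
                _accumulate(grads, g_grads, scale)
                total_loss += scale * g_loss

        if not np.isfinite(total_loss):
            raise TrainingDivergedError(
                f"non-finite loss {total_loss} at step {step}"
            )
        state["lr"] = _cosine_lr(step, cfg.steps, cfg.lr, cfg.lr_min)
        params_list, state = optim.optimizer_step(
            params_list, grads.param_list(), state
        )
        model.set_params(params_list)

        if step % cfg.log_every == 0 or step == cfg.steps - 1:
            rec = {"step": step, "loss": total_loss,
                   "elapsed": round(time.time() - t_start, 3)}
            trace.append(rec)
            if cfg.verbose:
                print(f"step {step:6d}  loss {total_loss:.6f}  "
                      f"elapsed {rec['elapsed']:.1f}s")

    f = make_file(model, meta)
    f.loss_trace = trace
    return f


def evaluate(img: ImageTensor, file: InifFile) -> dict:
    """PSNR/SSIM of the decoded reconstruction plus the achieved CR."""
    from .decoder import decode, ROISpec
    from .metrics import default_data_range, psnr, ssim

    decoded = decode(file, ROISpec.full())
    if decoded.shape != img.shape:
        raise ValueError("shape mismatch between image and stored model")
    rng_ = default_data_range(img.dtype_code)
    return {
        "psnr": psnr(img.data, decoded.data, data_range=rng_),
        "ssim": ssim(img.data, decoded.data, data_range=rng_),
        "mse": mse_loss(
            img.data.astype(np.float64).ravel(),
            decoded.data.astype(np.float64).ravel(),
        ),
        "achieved_cr": compression_ratio(img.raw_bytes, file.nbytes),
        "target_cr": file.header.get("target_cr"),
    }
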