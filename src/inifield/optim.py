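"""Pluggable parameter-update rules.

The reference method optimizes the coordinate network with a learned
optimizer (an ANN trained to propose updates), which removes learning-rate
tuning. Pretrained learned-optimizer weights are not distributable here,
so the registry ships robust hand-designed rules (adam, sgd) plus an
extension hook with the same signature, under which a learned optimizer
can be plugged in unchanged.
"""

from __future__ import annotations

import numpy as np


class OptimizerState(dict):
    """Opaque per-optimizer buffers plus a step index."""


def _init_common(optimizer_id, params, hyper, lr_scales=None):
    st = OptimizerState(optimizer_id=optimizer_id, step_index=0)
    st.update(hyper)
    st["lr_scales"] = list(lr_scales) if lr_scales is not None else [1.0] * len(params)
    return st


def _scales(state, n):
    s = state.get("lr_scales")
    return s if s is not None else [1.0] * n


def sgd_init(params, lr=1e-3, lr_scales=None, **_):
    return _init_common("sgd", params, {"lr": lr}, lr_scales)


def sgd_step(params, grads, state):
    lr = state["lr"]
    new = [
        p - (lr * s) * g.astype(p.dtype)
        for p, g, s in zip(params, grads, _scales(state, len(params)))
    ]
    state = OptimizerState(state)
    state["step_index"] += 1
    return new, state


def adam_init(params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, lr_scales=None, **_):
    st = _init_common(
        "adam", params,
        {"lr": lr, "beta1": beta1, "beta2": beta2, "eps": eps}, lr_scales,
    )
    st["m"] = [np.zeros_like(p, dtype=np.float32) for p in params]
    st["v"] = [np.zeros_like(p, dtype=np.float32) for p in params]
    return st


def adam_step(params, grads, state):
    state = OptimizerState(state)
    t = state["step_index"] + 1
    b1, b2, eps, lr = state["beta1"], state["beta2"], state["eps"], state["lr"]
    m = [b1 * m_ + (1 - b1) * g for m_, g in zip(state["m"], grads)]
    v = [b2 * v_ + (1 - b2) * g * g for v_, g in zip(state["v"], grads)]
    c1, c2 = 1 - b1**t, 1 - b2**t
    new = [
        (p - (lr * s) * (m_ / c1) / (np.sqrt(v_ / c2) + eps)).astype(p.dtype)
        for p, m_, v_, s in zip(params, m, v, _scales(state, len(params)))
    ]
    state["m"], state["v"] = m, v
    state["step_index"] = t
    return new, state


REGISTRY = {
    "sgd": (sgd_init, sgd_step),
    "adam": (adam_init, adam_step),
}


def register_optimizer(optimizer_id: str, init_fn, step_fn) -> None:
    """Extension hook: a learned optimizer registers the same signature."""
    REGISTRY[optimizer_id] = (init_fn, step_fn)


def make_state(optimizer_id: str, params, **hyper) -> OptimizerState:
    if optimizer_id not in REGISTRY:
        raise KeyError(f"unknown optimizer_id {optimizer_id!r}")
    return REGISTRY[optimizer_id][0](params, **hyper)


def optimizer_step(params, grads, state):
    """Apply one update; deterministic given (params, grads, state)."""
    oid = state["optimizer_id"]
    if oid not in REGISTRY:
        raise KeyError(f"unknown optimizer_id {oid!r}")
    if len(params) != len(grads) or any(
        p.shape != np.shape(g) for p, g in zip(params, grads)
    ):
        raise ValueError("grads do not match params")
    return REGISTRY[oid][1](params, grads, state)
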