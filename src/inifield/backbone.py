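"""Sinusoidal coordinate MLP: construction, forward pass and gradients.

The network maps a normalized coordinate vector to a pixel value.  Hidden
layers apply ``h -> sin(omega * (W h + b))`` with one trainable frequency
scalar per sine layer; the output layer is affine and unclipped.  ``depth``
counts weight layers: depth d >= 3 gives an input sine layer, d-2 hidden
sine layers and an affine head (d-1 sine layers and omegas in total).
``depth == 2`` degenerates to a single affine map with no sine layers —
this is the linear model used as the training loop's least-squares oracle.

Gradients are derived analytically (plain backprop through the sine chain)
and validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_OMEGA0 = 30.0


@dataclass
class SirenModel:
    in_dim: int
    out_dim: int
    width: int
    depth: int
    omega0: float
    weights: list = field(repr=False)
    biases: list = field(repr=False)
    omegas: np.ndarray = field(repr=False)

    @property
    def n_sine(self) -> int:
        return 0 if self.depth == 2 else self.depth - 1

    @property
    def dtype(self):
        return self.weights[0].dtype

    def param_list(self) -> list:
        """All trainable tensors in serialization order."""
        out = []
        for W, b in zip(self.weights, self.biases):
            out.append(W)
            out.append(b)
        out.append(self.omegas)
        return out

    def set_params(self, arrays) -> None:
        arrays = list(arrays)
        n = len(self.weights)
        for i in range(n):
            self.weights[i] = arrays[2 * i]
            self.biases[i] = arrays[2 * i + 1]
        self.omegas = arrays[2 * n]


def layer_dims(in_dim: int, out_dim: int, width: int, depth: int) -> list:
    """(fan_in, fan_out) of each weight layer."""
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if depth == 2:
        return [(in_dim, out_dim)]
    return (
        [(in_dim, width)]
        + [(width, width)] * (depth - 2)
        + [(width, out_dim)]
    )


def parameter_count_for(
    in_dim: int, out_dim: int, width: int, depth: int
) -> int:
    """Closed-form trainable scalar count, omegas included."""
    dims = layer_dims(in_dim, out_dim, width, depth)
    n = sum(fi * fo + fo for fi, fo in dims)
    return n + (0 if depth == 2 else depth - 1)


def parameter_count(model: SirenModel) -> int:
    return sum(int(p.size) for p in model.param_list())


def init_model(
    in_dim: int,
    out_dim: int = 1,
    width: int = 64,
    depth: int = 7,
    omega0: float = DEFAULT_OMEGA0,
    seed: int = 0,
    dtype=np.float32,
) -> SirenModel:
    """Initialize a SIREN: first layer uniform on [-1/in_dim, 1/in_dim],
    deeper layers uniform on +-sqrt(6/fan_in)/omega0, biases zero, all
    frequency scalars at omega0. Fully reproducible from the seed."""
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if in_dim < 1 or out_dim < 1 or width < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for li, (fi, fo) in enumerate(layer_dims(in_dim, out_dim, width, depth)):
        if li == 0:
            bound = 1.0 / fi
        else:
            bound = np.sqrt(6.0 / fi) / omega0
        weights.append(rng.uniform(-bound, bound, size=(fi, fo)).astype(dtype))
        biases.append(np.zeros(fo, dtype=dtype))
    n_sine = 0 if depth == 2 else depth - 1
    omegas = np.full(n_sine, omega0, dtype=dtype)
    return SirenModel(in_dim, out_dim, width, depth, omega0, weights, biases, omegas)


def _mm(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise batch-invariant matmul.

    BLAS falls back to gemv for single-column outputs, whose per-row
    results can depend on the batch size; a per-row pairwise reduction is
    bit-stable under any batching, which the decode contract requires.
    """
    if B.shape[1] == 1:
        return (A * B[:, 0]).sum(axis=1, keepdims=True)
    return A @ B


def _check_coords(model: SirenModel, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != model.in_dim:
        raise ValueError(
            f"coords shape {coords.shape} incompatible with in_dim {model.in_dim}"
        )
    return coords.astype(model.dtype, copy=False)


def forward(model: SirenModel, coords: np.ndarray) -> np.ndarray:
    """Evaluate the network at ``coords`` of shape (N, in_dim)."""
    h = _check_coords(model, coords)
    for l in range(model.n_sine):
        h = np.sin(model.omegas[l] * (_mm(h, model.weights[l]) + model.biases[l]))
    return _mm(h, model.weights[-1]) + model.biases[-1]


def forward_cached(model: SirenModel, coords: np.ndarray):
    """Forward pass keeping pre-activations for backprop."""
    h = _check_coords(model, coords)
    hs = [h]           # layer inputs
    pre = []           # a_l = W h + b before the frequency scaling
    for l in range(model.n_sine):
        a = _mm(hs[-1], model.weights[l]) + model.biases[l]
        pre.append(a)
        hs.append(np.sin(model.omegas[l] * a))
    y = _mm(hs[-1], model.weights[-1]) + model.biases[-1]
    return y, (hs, pre)


@dataclass
class Grads:
    weights: list
    biases: list
    omegas: np.ndarray

    def param_list(self) -> list:
        out = []
        for W, b in zip(self.weights, self.biases):
            out.append(W)
            out.append(b)
        out.append(self.omegas)
        return out


def backward(model: SirenModel, cache, d_out: np.ndarray) -> Grads:
    """Backpropagate ``d_out = dL/dy`` (N, out_dim) to parameter gradients."""
    hs, pre = cache
    dW = [None] * len(model.weights)
    db = [None] * len(model.biases)
    domega = np.zeros_like(model.omegas)
    d_out = np.asarray(d_out, dtype=model.dtype)

    dW[-1] = hs[-1].T @ d_out
    db[-1] = d_out.sum(axis=0)
    dh = d_out @ model.weights[-1].T
    for l in range(model.n_sine - 1, -1, -1):
        z = model.omegas[l] * pre[l]
        dz = dh * np.cos(z)
        domega[l] = np.sum(dz * pre[l])
        da = dz * model.omegas[l]
        dW[l] = hs[l].T @ da
        db[l] = da.sum(axis=0)
        dh = da @ model.weights[l].T
    return Grads(dW, db, domega)


def cast_model(model: SirenModel, dtype) -> SirenModel:
    """Copy with all parameters cast to ``dtype``."""
    return SirenModel(
        model.in_dim,
        model.out_dim,
        model.width,
        model.depth,
        model.omega0,
        [w.astype(dtype) for w in model.weights],
        [b.astype(dtype) for b in model.biases],
        model.omegas.astype(dtype),
    )
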