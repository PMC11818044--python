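"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (one protein graph per step, a few
hundred residues, hidden widths below a few hundred), so a compact
tape-based engine over dense float64 numpy arrays is sufficient and keeps
every training run bitwise reproducible on one machine.

Only the primitives the phosphosite model needs are implemented: affine
maps, ReLU/sigmoid, concatenation, row gathering, sequence shifts (for 1-D
convolution via shifted sums), per-row L2 normalization, batch/layer
normalization, and a numerically stable binary cross-entropy on logits.
Every primitive's gradient is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "matmul",
    "relu",
    "sigmoid",
    "concat",
    "take_rows",
    "shift_rows",
    "row_l2_normalize",
    "batch_norm",
    "layer_norm",
    "dropout",
    "bce_with_logits",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        other = _as_tensor(other)
        return add(self, scale(other, -1.0))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data * c

    def backward(g):
        _accumulate(a, g * c)

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        _accumulate(a, g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    data = _sigmoid(a.data)

    def backward(g):
        _accumulate(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def take_rows(a: Tensor, indices) -> Tensor:
    a = _as_tensor(a)
    idx = np.asarray(indices, dtype=np.intp)
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accumulate(a, ga)

    return _make(data, (a,), backward)


def shift_rows(a: Tensor, offset: int) -> Tensor:
    """out[i] = a[i - offset], rows shifted off the edge become zero."""
    a = _as_tensor(a)
    data = np.zeros_like(a.data)
    n = a.data.shape[0]
    if abs(offset) < n:
        if offset >= 0:
            data[offset:] = a.data[: n - offset]
        else:
            data[:offset] = a.data[-offset:]

    def backward(g):
        ga = np.zeros_like(a.data)
        if abs(offset) < n:
            if offset >= 0:
                ga[: n - offset] = g[offset:]
            else:
                ga[-offset:] = g[:offset]
        _accumulate(a, ga)

    return _make(data, (a,), backward)


def row_l2_normalize(a: Tensor, eps: float = 1e-12) -> Tensor:
    """Each row divided by max(||row||_2, eps)."""
    a = _as_tensor(a)
    norms = np.linalg.norm(a.data, axis=1, keepdims=True)
    denom = np.maximum(norms, eps)
    data = a.data / denom

    def backward(g):
        live = norms > eps
        inner = np.sum(data * g, axis=1, keepdims=True)
        ga = np.where(live, (g - data * inner) / denom, g / eps)
        _accumulate(a, ga)

    return _make(data, (a,), backward)


def batch_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-column standardization over the row axis, then affine (gamma, beta)."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    n = a.data.shape[0]
    mean = a.data.mean(axis=0)
    var = a.data.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mean) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(g):
        _accumulate(gamma, np.sum(g * xhat, axis=0))
        _accumulate(beta, np.sum(g, axis=0))
        dxhat = g * gamma.data
        ga = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * np.sum(dxhat * xhat, axis=0)
        )
        _accumulate(a, ga)

    return _make(data, (a, gamma, beta), backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row standardization over the column axis, then affine (gamma, beta)."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    d = a.data.shape[1]
    mean = a.data.mean(axis=1, keepdims=True)
    var = a.data.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mean) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(g):
        _accumulate(gamma, np.sum(g * xhat, axis=0))
        _accumulate(beta, np.sum(g, axis=0))
        dxhat = g * gamma.data
        ga = (inv_std / d) * (
            d * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * np.sum(dxhat * xhat, axis=1, keepdims=True)
        )
        _accumulate(a, ga)

    return _make(data, (a, gamma, beta), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return _as_tensor(a)
    a = _as_tensor(a)
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep) / keep

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, computed stably from logits."""
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    # softplus(z) - y*z, with softplus(z) = max(z,0) + log1p(exp(-|z|))
    losses = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z))) - y * z
    data = np.array(losses.mean())

    def backward(g):
        _accumulate(logits, g * (_sigmoid(z) - y) / z.size)

    return _make(data, (logits,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * p.grad
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
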