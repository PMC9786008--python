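"""Minimal reverse-mode automatic differentiation over numpy arrays.

The predictor's two encoder channels and its fusion head are trained by
gradient descent; this module supplies the tape-based autodiff needed for
that, restricted to the operations the model actually uses: broadcasting
arithmetic, (batched) matrix products, reductions, row gather/scatter for
embedding lookups and graph message passing, segment max for graph readout,
a numerically stable softmax, and the usual pointwise nonlinearities.

Gradients are dense float arrays of the same shape as each tensor's data.
Every primitive is exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "bce_with_logits",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1
    )
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = (
        "data",
        "grad",
        "requires_grad",
        "_parents",
        "_backward",
        "_grad_owned",
    )

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward
        self._grad_owned = False

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, True, parents, backward)
        return Tensor(data)

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution: hold a reference (may alias another tensor's
        # grad); copy lazily only if a second contribution arrives
        if self.grad is None:
            self.grad = np.asarray(g)
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def swap_last_axes(self) -> "Tensor":
        out_data = np.swapaxes(self.data, -1, -2)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, -1, -2))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- indexing ------------------------------------------------------------
    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows along axis 0 (embedding lookup / edge endpoint gather)."""
        idx = np.asarray(indices)
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return Tensor._make(out_data, (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows into `num_segments` buckets given per-row segment ids."""
        ids = np.asarray(segment_ids)
        out_data = np.zeros((num_segments,) + self.shape[1:], dtype=self.dtype)
        np.add.at(out_data, ids, self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[ids])

        return Tensor._make(out_data, (self,), backward)

    def segment_max(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Element-wise max of rows per segment; every segment must be nonempty.

        Gradient flows to the first row attaining each maximum (tie-break by
        row order), matching the convention of max-pool layers.
        """
        ids = np.asarray(segment_ids)
        out_data = np.full(
            (num_segments,) + self.shape[1:], -np.inf, dtype=self.dtype
        )
        np.maximum.at(out_data, ids, self.data)
        n_rows = self.shape[0]
        # first row index attaining the segment max, per (segment, column)
        row_idx = np.arange(n_rows).reshape((-1,) + (1,) * (self.ndim - 1))
        candidate = np.where(self.data == out_data[ids], row_idx, n_rows)
        winner = np.full((num_segments,) + self.shape[1:], n_rows)
        np.minimum.at(winner, ids, candidate)
        winner_mask = candidate == winner[ids]

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.where(winner_mask, g[ids], 0.0))

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, negative_slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.where(pos, g, negative_slope * g))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self) -> "Tensor":
        """Numerically stable softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                inner = (g * out_data).sum(axis=-1, keepdims=True)
                self._accumulate((g - inner) * out_data)

        return Tensor._make(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; call only in training mode."""
        if rate <= 0.0:
            return self
        keep = (rng.random(self.shape) >= rate).astype(self.dtype)
        scale = 1.0 / (1.0 - rate)
        return self * Tensor(keep * scale)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise binary cross-entropy on logits (numerically stable).

    loss = max(z, 0) - z*y + log(1 + exp(-|z|)); gradient = sigmoid(z) - y.
    """
    logits = as_tensor(logits)
    y = np.asarray(targets, dtype=logits.dtype)
    z = logits.data
    out_data = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - y))

    return Tensor._make(out_data, (logits,), backward)


class Adam:
    """Adam optimizer with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._buf = [np.empty_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
            p._grad_owned = False

    def step(self) -> None:
        """Classic Adam update, fused into preallocated buffers.

        Bias correction is folded into the step size:
        p -= lr_t * m / (sqrt(v) + eps_t) with
        lr_t = lr * sqrt(1-b2^t)/(1-b1^t), eps_t = eps * sqrt(1-b2^t),
        algebraically identical to the m_hat/v_hat formulation.
        """
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr2 = np.sqrt(1.0 - b2 ** self.t)
        lr_t = self.lr * corr2 / (1.0 - b1 ** self.t)
        eps_t = self.eps * corr2
        for p, m, v, buf in zip(self.params, self._m, self._v, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            np.multiply(g, g, out=buf)
            buf *= 1 - b2
            v += buf
            np.sqrt(v, out=buf)
            buf += eps_t
            np.divide(m, buf, out=buf)
            buf *= lr_t
            p.data -= buf
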