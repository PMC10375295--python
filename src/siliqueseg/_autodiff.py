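"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the EdgeConv segmentation network on a
CPU: tensors wrapping float32 arrays, a handful of differentiable ops
(matmul, broadcast add/mul, leaky ReLU, gather, concat, max-reductions,
softmax cross-entropy) and Adam. Gradients are accumulated by walking
the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "matmul", "add", "mul",
           "leaky_relu", "gather_rows", "concat", "max_axis",
           "reshape", "cross_entropy_mean"]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape))
        b._accumulate(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape))

    return _node(out_data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(-g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * np.where(mask, 1.0, slope).astype(np.float32))

    return _node(np.where(mask, x.data, slope * x.data), (x,), backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Rows of ``x`` at ``index`` (any integer-array shape); scatter-add
    gradient back to the source rows."""
    index = np.asarray(index)

    def backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index.ravel(), g.reshape(-1, g.shape[-1]))
        x._accumulate(acc)

    return _node(x.data[index], (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward)


def max_axis(x: Tensor, axis: int) -> Tensor:
    """Max-reduce one axis; gradient flows to the (first) argmax."""
    idx = np.expand_dims(x.data.argmax(axis=axis), axis)
    out_data = np.take_along_axis(x.data, idx, axis=axis).squeeze(axis)

    def backward(g):
        acc = np.zeros_like(x.data)
        np.put_along_axis(acc, idx, np.expand_dims(g, axis), axis=axis)
        x._accumulate(acc)

    return _node(out_data, (x,), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _node(x.data.reshape(shape), (x,), backward)


def cross_entropy_mean(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows of ``scores``.

    Per row: -log(exp(x[label]) / sum_j exp(x[j])), computed with the
    usual max-shift for stability.
    """
    labels = np.asarray(labels, dtype=int)
    n, c = scores.data.shape
    if labels.shape != (n,):
        raise ValueError("labels must be one per score row")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range")
    shifted = scores.data - scores.data.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    losses = log_z - shifted[np.arange(n), labels]
    softmax = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)

    def backward(g):
        grad = softmax.copy()
        grad[np.arange(n), labels] -= 1.0
        scores._accumulate(grad * (float(g) / n))

    return _node(np.float32(losses.mean()), (scores,), backward)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
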