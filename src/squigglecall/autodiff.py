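"""Minimal reverse-mode automatic differentiation on numpy arrays.

The basecalling network (residual convolutions, batch-normalized LSTMs,
CTC loss) is trained with plain numpy; this module supplies the tape.  It
implements exactly the primitives the network needs — broadcast-aware
arithmetic, matmul, the usual activations, reductions, slicing/concat and
a stride-1 same-padded 1-D convolution — each with a hand-written vector-
Jacobian product.  Gradients are validated against central finite
differences in the test suite.

Everything is double precision; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "batch_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(
        self,
        data,
        *,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        bw: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._bw = bw if self.requires_grad else None

    # ---- graph ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be tens of thousands deep
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
        self._accumulate(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)
            if node._parents:  # free interior grads/graph as we go
                node.grad = None
                node._parents = ()
                node._bw = None

    # ---- arithmetic -----------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._bw = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._bw = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._bw = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.shape))

        out._bw = bw
        return out

    # ---- activations ----------------------------------------------------

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._bw = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._bw = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._bw = lambda g: self._accumulate(g * mask)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._bw = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._bw = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    # ---- reductions / shape --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._bw = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._bw = lambda g: self._accumulate(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._bw = bw
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._bw = bw
    return out


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(B, T, C) -> (B, T, kernel*C) windows with same zero padding."""
    B, T, C = x.shape
    pad_left = (kernel - 1) // 2
    pad_right = kernel - 1 - pad_left
    xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
    # windows: (B, T, C, kernel) -> (B, T, kernel, C)
    return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, T, -1)


def conv1d(x: Tensor, weight: Tensor, kernel: int) -> Tensor:
    """Stride-1, same-zero-padded 1-D convolution with no bias.

    ``x`` is (B, T, C_in); ``weight`` is (kernel * C_in, C_out).  Output
    length always equals input length (the length-preservation contract of
    the convolutional stack).
    """
    B, T, C_in = x.shape
    cols = _im2col(x.data, kernel)  # (B, T, k*C_in)
    out_data = cols @ weight.data
    out = Tensor(out_data, parents=(x, weight))

    def bw(g):
        if weight.requires_grad:
            gw = np.einsum("btk,bts->ks", cols, g, optimize=True)
            weight._accumulate(gw)
        if x.requires_grad:
            gcols = g @ weight.data.T  # (B, T, k*C_in)
            gcols = gcols.reshape(B, T, kernel, C_in)
            pad_left = (kernel - 1) // 2
            gx = np.zeros((B, T + kernel - 1, C_in))
            for dk in range(kernel):
                gx[:, dk : dk + T] += gcols[:, :, dk]
            x._accumulate(gx[:, pad_left : pad_left + T])

    out._bw = bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor | None,
    running: dict,
    *,
    axes: tuple[int, ...],
    training: bool,
    eps: float = 1e-5,
    momentum: float = 0.1,
) -> Tensor:
    """Batch normalization  BN(x; gamma, beta) = beta + gamma * (x-E[x])/sqrt(Var[x]+eps).

    In training mode the statistics are those of the current mini-batch
    over ``axes``; exponential running averages are accumulated in
    ``running`` (keys ``mean``/``var``) and used verbatim in inference
    mode, making inference deterministic.  ``beta=None`` hard-codes a zero,
    non-trainable shift (used for the recurrent and input terms of the
    BN-LSTM, where a shift would be redundant with the cell bias).
    """
    if training:
        mu = x.mean(axis=axes, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        with np.errstate(invalid="ignore"):
            m = momentum
            running["mean"] = (1 - m) * running.get("mean", mu.data * 0) + m * mu.data
            running["var"] = (1 - m) * running.get("var", var.data * 0 + 1.0) + m * var.data
        inv = (var + eps) ** -0.5
        normed = centered * inv
    else:
        mu = running.get("mean", 0.0)
        var = running.get("var", 1.0)
        normed = (x - mu) * ((np.asarray(var) + eps) ** -0.5)
    out = normed * gamma
    if beta is not None:
        out = out + beta
    return out
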