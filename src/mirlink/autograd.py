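"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

The pair encoder needs exactly the operations defined here: broadcasting
arithmetic, (batched) matmul, the usual pointwise nonlinearities, softmax,
reductions, slicing/concat/stack, an embedding gather, a same-padding 1-D
convolution and max pooling. Everything is float32, single-threaded and
deterministic; gradients are accumulated on ``Tensor.grad`` by ``backward()``
over a topologically sorted tape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float32, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def _grad_buffer(self) -> np.ndarray:
        """Gradient array for in-place scatter accumulation."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _ensure(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor._ensure(other))

    def __rsub__(self, other):
        return Tensor._ensure(other) + (-self)

    def __mul__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                )

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (
            (lambda g: self._accum(g.reshape(orig))) if self.requires_grad else None
        )
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = (
            (lambda g: self._accum(g.transpose(*inv))) if self.requires_grad else None
        )
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            buf = self._grad_buffer()
            if isinstance(key, np.ndarray) or (
                isinstance(key, tuple) and any(isinstance(k, np.ndarray) for k in key)
            ):
                np.add.at(buf, key, g)
            else:
                buf[key] += g

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._grad_buffer()[...] += g

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = (
            (lambda g: self._accum(g * mask)) if self.requires_grad else None
        )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = (
            (lambda g: self._accum(g * y * (1.0 - y))) if self.requires_grad else None
        )
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (
            (lambda g: self._accum(g * (1.0 - y * y))) if self.requires_grad else None
        )
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (lambda g: self._accum(g * y)) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (
            (lambda g: self._accum(g / self.data)) if self.requires_grad else None
        )
        return out


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter."""
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    shape = shape if shape is not None else (fan_in, fan_out)
    return parameter(rng.uniform(-limit, limit, size=shape).astype(np.float32))


# ---------------------------------------------------------------------------
# composite / structural ops


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather from an embedding table; gradients scatter-add by id."""
    if ids.min() < 0 or ids.max() >= table.shape[0]:
        raise ValueError("token index out of vocabulary range")
    out = Tensor(table.data[ids], parents=(table,))

    def bw(g):
        if table.requires_grad:
            np.add.at(table._grad_buffer(), ids, g)

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 1-D convolution.

    x: (B, T, C_in); w: (K*C_in, F) laid out as K blocks of C_in; b: (F,).
    Output (B, T, F). Implemented as im2col + one GEMM.
    """
    B, T, c_in = x.shape
    kc, f = w.shape
    K = kc // c_in
    pad_l = (K - 1) // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,T,C,K)
    xcol = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * T, kc)
    y = (xcol @ w.data + b.data).reshape(B, T, f)
    out = Tensor(y, parents=(x, w, b))

    def bw(g):
        gf = g.reshape(B * T, f)
        if w.requires_grad:
            w._accum(xcol.T @ gf)
        if b.requires_grad:
            b._accum(gf.sum(axis=0))
        if x.requires_grad:
            dcol = (gf @ w.data.T).reshape(B, T, K, c_in)
            dxp = np.zeros_like(xp)
            for kk in range(K):
                dxp[:, kk : kk + T, :] += dcol[:, :, kk, :]
            x._accum(dxp[:, pad_l : pad_l + T, :])

    out._backward = bw
    return out


def max_pool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping temporal max pooling; trailing remainder dropped."""
    B, T, C = x.shape
    T2 = T // pool
    xt = x.data[:, : T2 * pool].reshape(B, T2, pool, C)
    idx = xt.argmax(axis=2)  # (B, T2, C)
    y = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(y, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gxt = np.zeros_like(xt)
        np.put_along_axis(gxt, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, : T2 * pool] = gxt.reshape(B, T2 * pool, C)
        x._accum(gx)

    out._backward = bw
    return out


def amax(x: Tensor, axis: int) -> Tensor:
    """Max reduction along one axis; gradient routes to the argmax entries."""
    idx = np.expand_dims(x.data.argmax(axis=axis), axis)
    y = np.take_along_axis(x.data, idx, axis=axis).squeeze(axis)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            buf = x._grad_buffer()
            np.put_along_axis(
                buf, idx, np.take_along_axis(buf, idx, axis=axis) + np.expand_dims(g, axis), axis=axis
            )

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
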