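"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainable layers in this package (relative self-attention, dilated
convolutions, the CRF loss) are expressed as compositions of the ``Tensor``
operations below.  The engine is deliberately small: a tape of ``Tensor``
nodes, each holding the numpy value, references to its parents and a closure
that accumulates vector-Jacobian products into the parents' ``grad`` buffers.

Only the operations the model needs are provided; every backward rule is
covered by the end-to-end finite-difference gradient check in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "einsum", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping an ``np.ndarray``."""

    __slots__ = ("data", "grad", "parents", "_vjp", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        vjp: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data)
        self.parents = parents
        self._vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None

    # -- graph -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node, accumulating into ``.grad``."""
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
            for p in node.parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def vjp(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, (self, other), vjp)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def vjp(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, (self,), vjp)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def vjp(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, (self, other), vjp)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._lift(other) ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def vjp(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, (self,), vjp)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def vjp(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(out_data, (self, other), vjp)

    # -- shaping -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def vjp(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor(out_data, (self,), vjp)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def vjp(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor(out_data, (self,), vjp)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def vjp(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(out_data, (self,), vjp)

    # -- reductions & nonlinearities --------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def vjp(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(out_data, (self,), vjp)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def vjp(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, (self,), vjp)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def vjp(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(out_data, (self,), vjp)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - inner))

        return Tensor(s, (self,), vjp)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        se = e.sum(axis=axis, keepdims=True)
        out_data = (np.log(se) + m)
        soft = e / se
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def vjp(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(gg * soft)

        return Tensor(out_data, (self,), vjp)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gain.data + bias.data
        d = self.shape[-1]

        def vjp(g):
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.shape))
            if self.requires_grad:
                gx = g * gain.data
                t1 = gx - gx.mean(axis=-1, keepdims=True)
                t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                self._accum(inv * (t1 - t2))
            _ = d  # d folded into the means above

        return Tensor(out_data, (self, gain, bias), vjp)

    def dropout(self, rate: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when ``rng`` is None (eval mode)."""
        if rng is None or rate <= 0.0:
            return self
        keep = (rng.random(self.shape) >= rate) / (1.0 - rate)
        return self * Tensor(keep.astype(self.data.dtype))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = list(tensors)
    out_data = np.concatenate([t.data for t in parts], axis=axis)
    sizes = [t.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for t, a, b in zip(parts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, tuple(parts), vjp)


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with the standard transpose-rule backward.

    Requires every index of each operand to appear in the output or in the
    other operand (true for all attention contractions used here).
    """
    in_subs, out_sub = subscripts.replace(" ", "").split("->")
    a_sub, b_sub = in_subs.split(",")
    out_data = np.einsum(subscripts, a.data, b.data)

    def vjp(g):
        if a.requires_grad:
            ga = np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data)
            a._accum(ga)
        if b.requires_grad:
            gb = np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data)
            b._accum(gb)

    return Tensor(out_data, (a, b), vjp)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 6e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
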