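"""Minimal reverse-mode automatic differentiation on numpy arrays.

The folding energies and the toy-scale networks in this package need
gradients of scalar objectives with respect to many array-valued
parameters.  This module provides a small tape-based reverse-mode engine:
a :class:`Tensor` wraps a float64 ``numpy`` array, arithmetic builds a
DAG, and :meth:`Tensor.backward` accumulates gradients by reverse
topological traversal.

Only the operations the package actually uses are implemented.  All
shapes follow numpy broadcasting; gradients of broadcast operands are
reduced back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "concatenate",
    "stack",
    "where_mask",
    "gradcheck",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the operand
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100.0  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjp = None  # callable(out_grad) -> tuple of parent grads

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves visited before their gradient arrived are handled above;
        # interior nodes keep no .grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = astensor(other)
        return Tensor._make(
            self.data + o.data,
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        o = astensor(other)
        return Tensor._make(
            self.data - o.data,
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)),
        )

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        o = astensor(other)
        return Tensor._make(
            self.data * o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = astensor(other)
        return Tensor._make(
            self.data / o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / o.data**2, o.shape),
            ),
        )

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor._make(
            self.data**p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        o = astensor(other)

        def vjp(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return Tensor._make(self.data @ o.data, (self, o), vjp)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        data = self.data[idx]
        shape = self.shape

        def vjp(g):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(data, (self,), vjp)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def sin(self):
        return Tensor._make(np.sin(self.data), (self,), lambda g: (g * np.cos(self.data),))

    def cos(self):
        return Tensor._make(np.cos(self.data), (self,), lambda g: (-g * np.sin(self.data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * sig,))

    def clip(self, lo=None, hi=None):
        """Clamp; gradient is zero outside [lo, hi] (flat extrapolation)."""
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def stop_gradient(self):
        return Tensor(self.data.copy())

    # -- composed ------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def norm(self, axis=-1, eps: float = 0.0, keepdims=False):
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps).sqrt()


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]

    def vjp(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, vjp)


def atan2(y: Tensor, x: Tensor) -> Tensor:
    y, x = astensor(y), astensor(x)
    denom = x.data**2 + y.data**2

    def vjp(g):
        return (
            _unbroadcast(g * x.data / denom, y.shape),
            _unbroadcast(-g * y.data / denom, x.shape),
        )

    return Tensor._make(np.arctan2(y.data, x.data), (y, x), vjp)


def einsum(spec: str, *operands) -> Tensor:
    """Einstein summation; no ellipsis, no repeated index within one operand."""
    operands = [astensor(t) for t in operands]
    in_specs, out_spec = spec.replace(" ", "").split("->")
    in_specs = in_specs.split(",")
    datas = [t.data for t in operands]
    out_data = np.einsum(spec, *datas)

    def vjp(g):
        grads = []
        for i, t in enumerate(operands):
            if not t.requires_grad:
                grads.append(None)
                continue
            others = [in_specs[j] for j in range(len(operands)) if j != i]
            other_data = [datas[j] for j in range(len(operands)) if j != i]
            back = f"{','.join([out_spec] + others)}->{in_specs[i]}"
            # indices of operand i summed out everywhere need explicit broadcast
            known = set(out_spec) | set("".join(others))
            missing = [c for c in in_specs[i] if c not in known]
            if missing:
                reduced = "".join(c for c in in_specs[i] if c in known)
                back = f"{','.join([out_spec] + others)}->{reduced}"
                gi = np.einsum(back, g, *other_data)
                # re-expand indices of operand i that appear nowhere else
                for pos, c in enumerate(in_specs[i]):
                    if c in missing:
                        gi = np.expand_dims(gi, axis=pos)
                gi = np.broadcast_to(gi, t.shape).copy()
            else:
                gi = np.einsum(back, g, *other_data)
            grads.append(gi)
        return tuple(grads)

    return Tensor._make(out_data, operands, vjp)


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Cross product over the last axis (size 3)."""
    a, b = astensor(a), astensor(b)
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return stack(
        [ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1
    )


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select with a constant boolean mask (not differentiable in mask)."""
    m = Tensor(np.asarray(mask, dtype=float))
    return m * a + (1.0 - m) * b


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gamma + beta


# ---------------------------------------------------------------------------


def gradcheck(fn, inputs, eps: float = 1e-6, rtol: float = 1e-5, atol: float = 1e-7):
    """Compare reverse-mode gradients of scalar ``fn(*inputs)`` against
    central finite differences.  ``inputs`` are Tensors with
    requires_grad=True.  Returns the max absolute deviation."""
    out = fn(*inputs)
    for t in inputs:
        t.zero_grad()
    out.backward()
    worst = 0.0
    for t in inputs:
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        nflat = num.ravel()
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            hi = fn(*inputs).item()
            flat[k] = orig - eps
            lo = fn(*inputs).item()
            flat[k] = orig
            nflat[k] = (hi - lo) / (2 * eps)
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        dev = np.abs(ana - num)
        tol = atol + rtol * np.abs(num)
        if not np.all(dev <= tol):
            worst = max(worst, float((dev - tol).max()))
    return worst
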