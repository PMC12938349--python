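"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The MIL networks in this package are small (a handful of dense layers over
bags of at most a few hundred instances), so a compact tape-based engine is
sufficient: every operation records its parents and a closure computing
vector-Jacobian products, and :meth:`Tensor.backward` walks the tape in
reverse topological order. All arithmetic is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._vjp = _vjp  # grad_out -> tuple of parent grads
        self.grad: np.ndarray | None = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parameter."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep for large cohorts)
        visit_stack: list[tuple[Tensor, bool]] = [(self, False)]
        while visit_stack:
            node, processed = visit_stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            visit_stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visit_stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        del stack  # noqa: F841

    def detach(self) -> np.ndarray:
        return self.data

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data
        sa, sb = self.data.shape, other.data.shape
        return Tensor(
            out_data,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a * b,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a / b,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data

        def vjp(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k,m) -> (m,)
                return g @ b.T, np.outer(a, g)
            if b.ndim == 1:  # (n,k) @ (k,) -> (n,)
                return np.outer(g, b), a.T @ g
            return g @ b.T, a.T @ g

        return Tensor(a @ b, _parents=(self, other), _vjp=vjp)

    # -- nonlinearities --------------------------------------------------------
    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor(
            np.where(mask, self.data, 0.0),
            _parents=(self,),
            _vjp=lambda g: (g * mask,),
        )

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor(np.log(a), _parents=(self,), _vjp=lambda g: (g / a,))

    # -- reductions / shaping --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self.data

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor(a.sum(axis=axis, keepdims=keepdims), _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(a_shape),),
        )

    def __getitem__(self, idx):
        a = self.data

        def vjp(g):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a[idx], _parents=(self,), _vjp=vjp)

    # -- composites --------------------------------------------------------------
    def softmax(self, axis=-1):
        """Numerically stable softmax; the max-shift is a constant w.r.t. grads."""
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=None, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if keepdims:
            return out
        target = np.squeeze(out.data, axis=axis).shape if axis is not None else ()
        return out.reshape(target)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def stack(tensors: list[Tensor]) -> Tensor:
    """Stack scalars / equal-shape tensors along a new leading axis."""
    tensors = [Tensor.as_tensor(t) for t in tensors]

    def vjp(g):
        return tuple(g[i] for i in range(len(tensors)))

    return Tensor(
        np.stack([t.data for t in tensors]), _parents=tuple(tensors), _vjp=vjp
    )
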