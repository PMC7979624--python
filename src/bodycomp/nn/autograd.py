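"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation networks in this package are trained with batch size 1 on
3D feature maps of shape ``(C, D, H, W)``.  This module provides the small
dynamic tape that backs them: a :class:`Tensor` wraps a float32 numpy array,
records the operations applied to it, and :meth:`Tensor.backward` replays
the tape in reverse topological order.

Only the primitives the architectures actually use are implemented (3D
convolution, instance normalization, ReLU, 2x2x2 max-pooling, factor-2
trilinear upsampling, channel concatenation, addition, softmax and the
supervision losses).  Each primitive carries a hand-derived adjoint that is
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

# Global switch: inference code paths disable taping to avoid retaining
# activations.  Use the `no_grad` context manager.
_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(out_value, parents, backward_fn) -> Tensor:
    """Wrap ``out_value`` in a Tensor wired to ``parents`` via ``backward_fn``.

    ``backward_fn(grad)`` must call ``_accumulate`` on each parent that
    requires a gradient.  When grad mode is off, the tape is not recorded.
    """
    out = Tensor(out_value)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def accumulate_grad(t: Tensor, g: np.ndarray) -> None:
    """Public hook for op implementations in sibling modules."""
    _accumulate(t, g)
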