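"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the deep archetype network: dense layers, tanh/relu
nonlinearities, softmax over either axis, and mean-squared-error losses.
Gradients are accumulated by a topologically ordered backward sweep over the
operation tape; correctness is checked against finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("value", "parents", "_backward", "grad", "requires_grad")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents
        self._backward = backward
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    # -- graph construction -------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        return Tensor(
            a.value @ b.value,
            (a, b),
            lambda g: (g @ b.value.T, a.value.T @ g),
        )

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

        return Tensor(a.value + b.value, (a, b), back)

    def __sub__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return _unbroadcast(g, a.value.shape), _unbroadcast(-g, b.value.shape)

        return Tensor(a.value - b.value, (a, b), back)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.value)
        return Tensor(y, (self,), lambda g: (g * (1.0 - y**2),))

    def relu(self) -> "Tensor":
        y = np.maximum(self.value, 0.0)
        return Tensor(y, (self,), lambda g: (g * (self.value > 0),))

    def softmax(self, axis: int) -> "Tensor":
        z = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def back(g: np.ndarray) -> tuple[np.ndarray]:
            return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

        return Tensor(y, (self,), back)

    def transpose(self) -> "Tensor":
        return Tensor(self.value.T, (self,), lambda g: (g.T,))

    def mse(self, target: np.ndarray) -> "Tensor":
        """Mean of squared elementwise differences against a constant target."""
        diff = self.value - np.asarray(target, dtype=float)
        n = diff.size

        def back(g: np.ndarray) -> tuple[np.ndarray]:
            return (g * 2.0 * diff / n,)

        return Tensor(np.array(np.mean(diff**2)), (self,), back)

    def __mul__(self, scalar: float) -> "Tensor":
        return Tensor(self.value * scalar, (self,), lambda g: (g * scalar,))

    # -- backward -----------------------------------------------------------

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node.parents, grads):
                if parent.requires_grad and g is not None:
                    parent.grad = parent.grad + g if parent.grad is not None else g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over broadcast dimensions back to the parent's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
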