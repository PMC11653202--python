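"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network here is small and fixed-shape (a couple of matrix products, a
leaky ReLU, a softmax attention, a cross-entropy), so a compact tape-based
engine is all the training loop needs. ``Tensor`` wraps an ndarray and
records a backward closure per operation; ``backward()`` walks the tape in
reverse topological order. Broadcasting follows numpy semantics; gradients
of broadcast operands are summed back to the operand's shape.

Only the operations the model uses are implemented: add, subtract,
multiply, matmul (including stacked/batched operands), transpose of the
last two axes, reshape, concatenate, leaky ReLU, dropout, row softmax, and
a fused masked softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: the tape can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operations ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    def __sub__(self, other: "Tensor") -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.data.shape))

        return Tensor._make(self.data - other.data, (self, other), bw)

    def __mul__(self, other):
        if not isinstance(other, Tensor):  # scalar
            c = float(other)

            def bw_scalar(g):
                if self.requires_grad:
                    self._accumulate(c * g)

            return Tensor._make(self.data * c, (self,), bw_scalar)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
                other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(a @ b, (self, other), bw)

    __matmul__ = matmul

    def transpose_last(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, -1, -2))

        return Tensor._make(np.swapaxes(self.data, -1, -2), (self,), bw)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def leaky_relu(self, slope: float = 0.25) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(
            np.where(mask, self.data, slope * self.data), (self,), bw
        )

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; the mask is drawn from ``rng`` at call time."""
        if rate <= 0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return Tensor._make(self.data * keep, (self,), bw)

    def softmax_last(self) -> "Tensor":
        x = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(x)
        s = e / e.sum(axis=-1, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accumulate(s * (g - dot))

        return Tensor._make(s, (self,), bw)

    def concat_with(self, others: list["Tensor"], axis: int = -1) -> "Tensor":
        return concat([self, *others], axis=axis)

    def sum(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(), (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def masked_cross_entropy(logits: Tensor, labels: np.ndarray, rows: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``logits[rows]`` against integer ``labels[rows]``.

    Fused log-softmax + negative log-likelihood; the gradient is
    (softmax - onehot) / len(rows) on the selected rows and zero elsewhere.
    """
    rows = np.asarray(rows, dtype=int)
    y = np.asarray(labels, dtype=int)[rows]
    z = logits.data[rows]
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(len(rows)), y].mean()

    def bw(g):
        if logits.requires_grad:
            grad = np.zeros_like(logits.data)
            p = np.exp(logp)
            p[np.arange(len(rows)), y] -= 1.0
            grad[rows] = p / len(rows)
            logits._accumulate(float(g) * grad)

    return Tensor._make(loss, (logits,), bw)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> Parameter:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class Adam:
    """Standard Adam on a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
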