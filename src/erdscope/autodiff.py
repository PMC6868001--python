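"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The networks used in this package are small (a few convolution blocks along
the frequency axis plus dense heads), so a compact tape-based engine is
sufficient: each :class:`Tensor` records its parents and a backward closure,
and :meth:`Tensor.backward` walks the tape in reverse topological order.
Gradients are plain ``numpy`` arrays accumulated into ``Tensor.grad``.

Only the operations the models need are provided: broadcast arithmetic,
matrix multiplication, ReLU, reshape, reductions, log-softmax, label
selection, and 1D/2D valid convolution and max-pooling.  All convolution
kernels are small, so their backward passes loop over kernel taps rather
than materialising im2col buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "log_softmax",
    "pick",
    "conv1d",
    "maxpool1d",
    "conv2d",
    "maxpool2d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name
        self._grad_owned = False

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: nets can be deep-ish
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
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # First accumulation adopts the incoming array without copying; it is
        # only mutated in place once this node owns a private buffer.
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def log_softmax(x: Tensor) -> Tensor:
    """Log-softmax along the last axis, computed stably via log-sum-exp."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = Tensor(ls, parents=(x,))

    def bwd(g):
        x._accum(g - np.exp(ls) * g.sum(axis=-1, keepdims=True))

    out._backward = bwd
    return out


def pick(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select ``x[i, idx[i]]`` for each row i (label log-probability lookup)."""
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(x.data.shape[0])
    out = Tensor(x.data[rows, idx], parents=(x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (rows, idx), g)
        x._accum(gx)

    out._backward = bwd
    return out


def _conv1d_matrix(w: np.ndarray, L: int, Lp: int) -> np.ndarray:
    """Dense (Cin*L, Cout*Lp) band matrix realizing a valid 1D correlation.

    The kernel and channel counts here are tiny while the batch is large, so
    folding the convolution into one GEMM against this matrix is far faster
    than any per-tap loop: the input can stay in its natural (N, Cin*L)
    contiguous layout throughout.
    """
    Cout, Cin, k = w.shape
    W = np.zeros((Cin * L, Cout * Lp), dtype=w.dtype)
    for o in range(Cout):
        for i in range(Cin):
            for j in range(k):
                np.fill_diagonal(W[i * L + j:i * L + j + Lp,
                                   o * Lp:(o + 1) * Lp], w[o, i, j])
    return W


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1D correlation: x (N, Cin, L), w (Cout, Cin, k), b (Cout,)."""
    N, Cin, L = x.data.shape
    Cout, _, k = w.data.shape
    Lp = L - k + 1
    if Lp < 1:
        raise ValueError(f"kernel {k} longer than input {L}")
    Wbig = _conv1d_matrix(w.data, L, Lp)
    x2 = x.data.reshape(N, Cin * L)
    out_data = (x2 @ Wbig).reshape(N, Cout, Lp) + b.data[None, :, None]
    out = Tensor(out_data, parents=(x, w, b))

    def bwd(g):
        g2 = g.reshape(N, Cout * Lp)
        x._accum((g2 @ Wbig.T).reshape(N, Cin, L))
        gWbig = x2.T @ g2
        gw = np.empty_like(w.data)
        for o in range(Cout):
            for i in range(Cin):
                for j in range(k):
                    gw[o, i, j] = gWbig[i * L + j:i * L + j + Lp,
                                        o * Lp:(o + 1) * Lp].diagonal().sum()
        w._accum(gw)
        b._accum(g.sum(axis=(0, 2)))

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max-pooling along the last axis; trailing remainder dropped."""
    N, C, L = x.data.shape
    Lq = L // k
    blocks = x.data[:, :, :Lq * k].reshape(N, C, Lq, k)
    vals = blocks[..., 0]
    for j in range(1, k):  # pairwise maximum beats reduce/argmax for tiny k
        vals = np.maximum(vals, blocks[..., j])
    out = Tensor(vals, parents=(x,))

    def bwd(g):
        # route the gradient to maximal positions (ties, a measure-zero
        # event for continuous inputs, receive duplicate credit)
        mask = blocks == vals[..., None]
        gx = np.zeros_like(x.data)
        gx[:, :, :Lq * k] = (mask * g[..., None]).reshape(N, C, Lq * k)
        x._accum(gx)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 2D correlation: x (N, Cin, H, W), w (Cout, Cin, kh, kw), b (Cout,)."""
    N, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    Hp, Wp = H - kh + 1, W - kw + 1
    if Hp < 1 or Wp < 1:
        raise ValueError("kernel larger than input")
    out_data = np.zeros((N, Cout, Hp, Wp), dtype=x.data.dtype)
    for u in range(kh):
        for v in range(kw):
            out_data += np.einsum("nihw,oi->nohw",
                                  x.data[:, :, u:u + Hp, v:v + Wp], w.data[:, :, u, v])
    out_data += b.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, w, b))

    def bwd(g):
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for u in range(kh):
            for v in range(kw):
                gx[:, :, u:u + Hp, v:v + Wp] += np.einsum("nohw,oi->nihw", g, w.data[:, :, u, v])
                gw[:, :, u, v] = np.einsum("nohw,nihw->oi", g, x.data[:, :, u:u + Hp, v:v + Wp])
        x._accum(gx)
        w._accum(gw)
        b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def maxpool2d(x: Tensor, k: int) -> Tensor:
    N, C, H, W = x.data.shape
    Hq, Wq = H // k, W // k
    blocks = x.data[:, :, :Hq * k, :Wq * k].reshape(N, C, Hq, k, Wq, k)
    blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Hq, Wq, k * k)
    arg = blocks.argmax(axis=-1)
    vals = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    out = Tensor(vals, parents=(x,))

    def bwd(g):
        gb = np.zeros((N, C, Hq, Wq, k * k), dtype=x.data.dtype)
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        gb = gb.reshape(N, C, Hq, Wq, k, k).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, :Hq * k, :Wq * k] = gb.reshape(N, C, Hq * k, Wq * k)
        x._accum(gx)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer with the usual defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
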