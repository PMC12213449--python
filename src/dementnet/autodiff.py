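"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides the tensor type, neural-network layers (linear, layer norm,
multi-head self-attention) and the Adam optimizer used by the image
encoder and patient-level classifier. The engine is tape-based: each
``Tensor`` records its parents and a backward closure; ``backward()``
walks the tape in reverse topological order. Everything runs in float64
on a single CPU, which is adequate for the small transformer geometries
this package trains.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
    "concat",
    "stack",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * (1 - val ** 2),)
        return out

    def relu(self):
        val = np.maximum(self.data, 0.0)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        t = np.tanh(c * (x + 0.044715 * x ** 3))
        val = 0.5 * x * (1 + t)
        out = Tensor(val, self.requires_grad, (self,))

        def backward(g):
            dt = (1 - t ** 2) * c * (1 + 3 * 0.044715 * x ** 2)
            return (g * (0.5 * (1 + t) + 0.5 * x * dt),)

        out._backward = backward
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val * (1 - val),)
        return out

    def sqrt(self):
        return self ** 0.5

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, self.requires_grad, (self,))

        def backward(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            return (val * (g - dot),)

        out._backward = backward
        return out

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if isinstance(t, Parameter) or t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    out._backward = backward
    return out


# =========================================================================
# Layers
# =========================================================================


class Module:
    def parameters(self) -> list:
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Pre-norm multi-head self-attention over (..., T, D) token arrays.

    An additive mask of shape (..., T) with 0 for attended and -inf
    (large negative) for excluded positions may be supplied. The softmax
    attention weights of the most recent forward pass are kept (as plain
    arrays) in ``last_attention`` for interpretation.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention = None  # (..., heads, T, T)

    def forward(self, x: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        T, D = x.shape[-2], x.shape[-1]
        H, hd = self.n_heads, D // self.n_heads
        lead = x.shape[:-2]
        qkv = self.qkv(x)                               # (..., T, 3D)
        qkv = qkv.reshape(*lead, T, 3 * H, hd)
        qkv = qkv.swapaxes(-3, -2)                      # (..., 3H, T, hd)
        q = qkv[..., 0:H, :, :]
        k = qkv[..., H:2 * H, :, :]
        v = qkv[..., 2 * H:3 * H, :, :]
        att = (q @ k.swapaxes(-1, -2)) * (hd ** -0.5)   # (..., H, T, T)
        if mask_bias is not None:
            att = att + Tensor(mask_bias[..., None, None, :])
        w = att.softmax(axis=-1)
        self.last_attention = w.data.copy()
        out = w @ v                                     # (..., H, T, hd)
        out = out.swapaxes(-3, -2).reshape(*lead, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def __call__(self, x: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        x = x + self.attn.forward(self.ln1(x), mask_bias)
        x = x + self.fc2(self.fc1(self.ln2(x)).gelu())
        return x


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
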