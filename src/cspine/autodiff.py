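"""Minimal reverse-mode automatic differentiation on numpy arrays.

All tensors are float32. The graph is built eagerly; ``Tensor.backward``
runs a topological sweep. Only the operations needed by the volumetric
networks in this package are provided (dense algebra, pointwise
nonlinearities, softmax, reductions, slicing/gather, concatenation,
3-D convolution via im2col and a stride-2 kernel-2 transposed
convolution for upsampling).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "as_tensor",
    "concat",
    "stack",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "GroupNorm",
    "Conv3d",
    "ConvTranspose3d",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
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

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            # post-order without recursion
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # own a fresh buffer (g may alias another node's grad)
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data,
                                              other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data**2,
                                              other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, expo: float):
        out = self._make(self.data ** expo, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * expo * self.data ** (expo - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                a, b = self.data, other.data
                if self.requires_grad:
                    ga = g @ b.swapaxes(-1, -2)
                    self._accum(_unbroadcast(ga, a.shape))
                if other.requires_grad:
                    gb = a.swapaxes(-1, -2) @ g
                    other._accum(_unbroadcast(gb, b.shape))
            out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = self._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:
            basic = isinstance(idx, (slice, int)) or (
                isinstance(idx, tuple)
                and all(isinstance(i, (slice, int)) for i in idx))

            def bw(g):
                full = np.zeros_like(self.data)
                if basic:
                    full[idx] += g  # slices cannot repeat positions
                else:
                    np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims),
                         (self,), None)
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise ------------------------------------------------------
    def exp(self):
        ed = np.exp(self.data)
        out = self._make(ed, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * ed)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        sd = np.sqrt(self.data)
        out = self._make(sd, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / np.maximum(sd, 1e-12))
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        from scipy.special import expit
        s = expit(self.data)
        out = self._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def clip(self, lo: float, hi: float):
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accum(g * mask)
        return out

    def maximum(self, other):
        """Elementwise max against a constant (hinge); grad flows to self only
        where self wins (ties go to self)."""
        c = np.asarray(other, dtype=np.float32)
        out = self._make(np.maximum(self.data, c), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data >= c))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        ez = np.exp(z)
        s = ez / ez.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)
        if out.requires_grad:
            def bw(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
            out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)
        out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = as_tensor(t)
        expanded.append(t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]))
    return concat(expanded, axis=axis)


# ---------------------------------------------------------------------------
# 3-D convolution ops (NCDHW layout)
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """3-D convolution, stride 1. x: (N,C,D,H,W); w: (Co,C,k,k,k)."""
    x = as_tensor(x)
    w = as_tensor(w)
    N, C, D, H, W = x.shape
    Co, Ci, k, _, _ = w.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((padding, padding),) * 3) \
        if padding else x.data
    Do, Ho, Wo = (xp.shape[2] - k + 1, xp.shape[3] - k + 1, xp.shape[4] - k + 1)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                   axis=(2, 3, 4))
    # (N, C, Do, Ho, Wo, k,k,k) -> (N, Do*Ho*Wo, C*k^3)
    col = np.ascontiguousarray(
        win.transpose(0, 2, 3, 4, 1, 5, 6, 7), dtype=np.float32).reshape(
        N, Do * Ho * Wo, C * k ** 3)
    wm = w.data.reshape(Co, C * k ** 3)
    y = col @ wm.T  # (N, L, Co)
    y = y.transpose(0, 2, 1).reshape(N, Co, Do, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1, 1)
    out = Tensor(y)
    parents = (x, w) + ((b,) if b is not None else ())
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents

        def bw(g):
            gl = g.reshape(N, Co, Do * Ho * Wo).transpose(0, 2, 1)  # (N,L,Co)
            if w.requires_grad:
                gw = np.einsum("nlo,nlc->oc", gl, col, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                gcol = gl @ wm  # (N, L, C*k^3)
                gcol = gcol.reshape(N, Do, Ho, Wo, C, k, k, k)
                gx = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            gx[:, :, i:i + Do, j:j + Ho, l:l + Wo] += \
                                gcol[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding,
                            padding:-padding]
                x._accum(gx)
        out._backward = bw
    return out


def conv_transpose3d_s2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed 3-D convolution, kernel 2, stride 2 (exact 2x upsampling).

    x: (N,C,D,H,W); w: (C,Co,2,2,2); output (N,Co,2D,2H,2W).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    N, C, D, H, W = x.shape
    Ci, Co = w.shape[:2]
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    t = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    y = t.reshape(N, Co, 2 * D, 2 * H, 2 * W)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1, 1)
    out = Tensor(y)
    parents = (x, w) + ((b,) if b is not None else ())
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents

        def bw(g):
            gt = g.reshape(N, Co, D, 2, H, 2, W, 2)
            if x.requires_grad:
                x._accum(np.einsum("nodihjwk,coijk->ncdhw", gt, w.data,
                                   optimize=True))
            if w.requires_grad:
                w._accum(np.einsum("nodihjwk,ncdhw->coijk", gt, x.data,
                                   optimize=True))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive discovery, torch-style."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            self._collect(obj, params, seen)
        return params

    @staticmethod
    def _collect(obj, params, seen):
        if isinstance(obj, Parameter):
            if id(obj) not in seen:
                seen.add(id(obj))
                params.append(obj)
        elif isinstance(obj, Module):
            for p in obj.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        elif isinstance(obj, (list, tuple)):
            for item in obj:
                Module._collect(item, params, seen)
        elif isinstance(obj, dict):
            for item in obj.values():
                Module._collect(item, params, seen)

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, obj in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(obj, Parameter):
                out[key] = obj
            elif isinstance(obj, Module):
                out.update(obj.named_parameters(prefix=key + "."))
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        missing = set(named) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.w = Parameter(_init(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d, dtype=np.float32))
        self.beta = Parameter(np.zeros(d, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class GroupNorm(Module):
    """Group normalization over channel groups of an (N,C,D,H,W) tensor."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must divide into groups")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        N, C, D, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g, D, H, W)
        mu = xg.mean(axis=(2, 3, 4, 5), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4, 5), keepdims=True)
        xhat = (xc / (var + self.eps).sqrt()).reshape(N, C, D, H, W)
        return xhat * self.gamma.reshape(1, C, 1, 1, 1) \
            + self.beta.reshape(1, C, 1, 1, 1)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, padding: int | None = None):
        fan = c_in * k ** 3
        self.w = Parameter(_init(rng, (c_out, c_in, k, k, k), fan))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))
        self.padding = (k // 2) if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, padding=self.padding)


class ConvTranspose3d(Module):
    """Kernel-2 / stride-2 transposed convolution (2x upsampler)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = Parameter(_init(rng, (c_in, c_out, 2, 2, 2), c_in * 8))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d_s2(x, self.w, self.b)


class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Checkpoint container: .npz of parameter arrays + JSON config header
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict[str, np.ndarray], config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(Path(path)) as npz:
        config = json.loads(bytes(npz["__config__"].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    return state, config
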