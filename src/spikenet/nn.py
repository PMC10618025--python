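"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The networks in this package are deliberately small (they train on a CPU in
minutes), so the engine favours clarity over generality: a :class:`Tensor`
wraps an ``ndarray`` and records a closure-based backward graph; convolutions
use an im2col/col2im pair; the optimizer is plain SGD with momentum and weight
decay, matching the training recipe used throughout.

Only the operations the detector and the color-transform network actually
need are implemented.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "Linear",
    "SGD",
    "concat",
    "bce_with_logits",
]


def _as_float(data):
    a = np.asarray(data)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- basic info --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def arctan(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data**2))

        return Tensor._make(np.arctan(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    def minimum(self, other):
        other = self._coerce(other)
        take_self = self.data <= other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), bwd)

    def maximum(self, other):
        other = self._coerce(other)
        take_self = self.data >= other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return Tensor._make(s, (self,), bwd)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        return Tensor._make(self.data[idx], (self,), bwd)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of an (N, C, H, W) tensor."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        n, c, h, w = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(out_data, (self,), bwd)

    # -- linear algebra --------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- convolution -------------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1, pad: int = 0):
        """2-D convolution of an (N, Cin, H, W) tensor.

        ``weight`` is (Cout, Cin, kh, kw); ``pad`` is symmetric zero padding.
        """
        x = self.data
        wd = weight.data
        cout, cin, kh, kw = wd.shape
        if x.shape[1] != cin:
            raise ValueError(f"channel mismatch: input has {x.shape[1]}, weight expects {cin}")
        if pad:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        else:
            xp = x
        n, _, hp, wp = xp.shape
        oh = (hp - kh) // stride + 1
        ow = (wp - kw) // stride + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # (N, Cin, oh, ow, kh, kw) -> (N*oh*ow, Cin*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, cin * kh * kw)
        wmat = wd.reshape(cout, cin * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out = out + bias.data
        out_data = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def bwd(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if weight.requires_grad:
                weight._accum((gmat.T @ cols).reshape(wd.shape))
            if self.requires_grad:
                dcols = (gmat @ wmat).reshape(n, oh, ow, cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += dcols[:, :, i, j]
                if pad:
                    dxp = dxp[:, :, pad:-pad, pad:-pad]
                self._accum(dxp)

        return Tensor._make(out_data, parents, bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Element-wise binary cross-entropy on logits (numerically stable).

    Targets may be soft (e.g. a circular smooth label vector); no reduction
    is applied — call ``.mean()`` on the result.
    """
    t = targets.data if isinstance(targets, Tensor) else np.asarray(targets, dtype=logits.data.dtype)
    x = logits.data
    out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def bwd(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-x))
            logits._accum(g * (s - t))

    return Tensor._make(out_data, (logits,), bwd)


# ---------------------------------------------------------------------------
# Modules and optimizer
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery by attribute walk, checkpoint dicts."""

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for mod in self.modules():
            if hasattr(mod, "training"):
                mod.training = True
        return self

    def eval(self):
        for mod in self.modules():
            if hasattr(mod, "training"):
                mod.training = False
        return self

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if name == "_buffers" and isinstance(val, dict):
                for k, arr in val.items():
                    yield f"{prefix}{k}", val, k
            elif isinstance(val, Module):
                yield from val.named_buffers(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, buf, key in self.named_buffers():
            d[f"buf:{name}"] = buf[key].copy()
        return d

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for k, p in own.items():
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {state[k].shape} vs {p.data.shape}")
            p.data = state[k].astype(p.data.dtype).copy()
        for name, buf, key in self.named_buffers():
            sk = f"buf:{name}"
            if sk in state:
                buf[key] = state[sk].copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad=None,
                 rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization for (N, C, H, W) tensors.

    Training mode normalizes by batch statistics (autodiff flows through
    them) and maintains exponential running estimates; eval mode uses the
    running estimates, so inference is deterministic and batch-independent.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self._buffers = {"running_mean": np.zeros(c, dtype=np.float32),
                         "running_var": np.ones(c, dtype=np.float32)}
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mean.data.reshape(c)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(c)
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            rm = self._buffers["running_mean"].reshape(1, c, 1, 1)
            rv = self._buffers["running_var"].reshape(1, c, 1, 1)
            xhat = (x - rm) * (1.0 / np.sqrt(rv + self.eps))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBnAct(Module):
    """Convolution + batch norm + leaky ReLU, the detector's basic block."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator = None, act: bool = True):
        self.conv = Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.norm = BatchNorm2d(cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return y.leaky_relu() if self.act else y


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight.transpose(1, 0)) + self.bias


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
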