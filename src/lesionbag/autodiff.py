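"""Compact reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a ``Tensor`` holding a NumPy
array plus a backward closure, a small set of differentiable operations
(elementwise algebra, matmul, un-padded strided convolution, transposed
convolution, batch normalization, log-softmax), a ``Module`` container
system, and an SGD optimizer with momentum and weight decay.

Only what the bag-of-local-features model needs is implemented. All
convolutions are "valid" (no padding), matching the backbone's design,
and gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "SGD",
    "no_grad",
    "concat",
    "log_softmax",
    "relu",
    "sigmoid",
    "global_avg_pool",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad() -> Iterator[None]:
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (50+ conv layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- operator sugar ------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) != 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def relu(self):
        return relu(self)

    def sigmoid(self):
        return sigmoid(self)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_graph(*tensors: Tensor) -> bool:
    return _grad_enabled and any(
        t.requires_grad or t._backward is not None for t in tensors
    )


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


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
    return grad.reshape(shape)


# -- elementwise & shape ops ------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    if isinstance(exponent, Tensor):
        raise TypeError("only scalar exponents are supported")
    data = a.data ** exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1)),)

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return ((a, g * data),)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        return ((a, g * mask),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * data * (1.0 - data)),)

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.data.shape).copy()),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.data.shape)),)

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), backward)


def take(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return _make(data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    data = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _make(data, (a, b), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - logz
    softmax = np.exp(data)

    def backward(g):
        return ((a, g - softmax * g.sum(axis=axis, keepdims=True)),)

    return _make(data, (a,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return tmean(x, axis=(2, 3))


# -- convolution ops --------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, s: int):
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    v = v[:, :, ::s, ::s]
    n, c, oh, ow = v.shape[:4]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * kh * kw, oh * ow
    )
    return cols, oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, s: int, oh: int, ow: int):
    n, c, h, w = xshape
    dx = np.zeros(xshape, dtype=dcols.dtype)
    dc = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dc[:, :, i, j]
    return dx


def conv2d(x, w, b=None, stride: int = 1) -> Tensor:
    """Valid (un-padded) 2-D convolution. x: (N,C,H,W); w: (O,C,kh,kw)."""
    x, w = _as_tensor(x), _as_tensor(w)
    o, c, kh, kw = w.data.shape
    if x.data.shape[1] != c:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, weight expects {c}"
        )
    cols, oh, ow = _im2col(x.data, kh, kw, stride)
    w2 = w.data.reshape(o, -1)
    out = np.matmul(w2, cols)  # (N, O, OH*OW)
    if b is not None:
        out = out + _as_tensor(b).data.reshape(1, o, 1)
    data = out.reshape(x.data.shape[0], o, oh, ow)
    parents = (x, w) if b is None else (x, w, _as_tensor(b))

    def backward(g):
        g2 = g.reshape(g.shape[0], o, oh * ow)
        dw = np.einsum("nop,nkp->ok", g2, cols, optimize=True).reshape(w.data.shape)
        dcols = np.matmul(w2.T, g2)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, oh, ow)
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((parents[2], g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return _make(data, parents, backward)


def conv_transpose2d(x, w, b=None, stride: int = 1) -> Tensor:
    """Transposed convolution. x: (N,C,H,W); w: (C,O,kh,kw).

    Output spatial size is (H-1)*stride + kh per side (adjoint of the
    un-padded strided convolution).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    c, o, kh, kw = w.data.shape
    if x.data.shape[1] != c:
        raise ValueError(
            f"conv_transpose2d channel mismatch: input has {x.data.shape[1]}, "
            f"weight expects {c}"
        )
    n, _, h, wd = x.data.shape
    ho, wo = (h - 1) * stride + kh, (wd - 1) * stride + kw
    w2 = w.data.reshape(c, o * kh * kw)
    cols = np.matmul(w2.T, x.data.reshape(n, c, h * wd))  # (N, O*kh*kw, H*W)
    out = _col2im(cols, (n, o, ho, wo), kh, kw, stride, h, wd)
    if b is not None:
        out = out + _as_tensor(b).data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, _as_tensor(b))

    def backward(g):
        # gather the kernel-footprint windows of g back onto the input grid
        gc = np.empty((n, o, kh, kw, h, wd), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gc[:, :, i, j] = g[:, :, i : i + stride * h : stride, j : j + stride * wd : stride]
        gcols = gc.reshape(n, o * kh * kw, h * wd)
        dx = np.matmul(w2, gcols).reshape(x.data.shape)
        dw = (
            np.matmul(x.data.reshape(n, c, h * wd), gcols.transpose(0, 2, 1))
            .sum(axis=0)
            .reshape(w.data.shape)
        )
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((parents[2], g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return _make(data := out, parents, backward)


def batch_norm2d(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    update_stats: bool = True,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays mutated in place when
    ``training and update_stats`` (frozen on the SAM perturbation pass).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        if update_stats:
            m = n * h * w
            unbiased = var * (m / max(m - 1, 1))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            running_var *= 1.0 - momentum
            running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gscaled = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            gsum = gscaled.sum(axis=(0, 2, 3), keepdims=True)
            gx_xhat = (gscaled * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (
                inv_std.reshape(1, c, 1, 1)
                * (gscaled - gsum / m - xhat * gx_xhat / m)
            )
        else:
            dx = gscaled * inv_std.reshape(1, c, 1, 1)
        return ((x, dx), (gamma, dgamma), (beta, dbeta))

    return _make(data, (x, gamma, beta), backward)


# -- module system ----------------------------------------------------


class Module:
    """Container with recursive parameter/buffer discovery and train/eval."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif name in getattr(self, "_buffer_names", ()):
                yield full, value

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name]).copy()
        for holder, attr, full in self._buffer_slots():
            setattr(holder, attr, np.asarray(state[full]).copy())

    def _buffer_slots(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._buffer_slots(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._buffer_slots(f"{full}.{i}.")
            elif name in getattr(self, "_buffer_names", ()):
                yield self, name, full

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_he_normal(rng, (in_features, out_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        self.stride = stride
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size),
                       fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        self.stride = stride
        fan_in = in_channels
        self.weight = Parameter(
            _he_normal(rng, (in_channels, out_channels, kernel_size, kernel_size),
                       fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features, dtype=dtype))
        self.bias = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.update_stats = True

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            training=self.training, update_stats=self.update_stats,
            momentum=self.momentum, eps=self.eps,
        )


def freeze_bn_stats(module: Module):
    """Context manager: suspend running-statistic updates in all BN layers."""

    @contextlib.contextmanager
    def ctx():
        bns = [m for m in module.modules() if isinstance(m, BatchNorm2d)]
        prev = [bn.update_stats for bn in bns]
        for bn in bns:
            bn.update_stats = False
        try:
            yield
        finally:
            for bn, p in zip(bns, prev):
                bn.update_stats = p

    return ctx()


# -- optimizer --------------------------------------------------------


class SGD:
    """SGD with momentum and (decoupled-from-loss, coupled-to-grad) weight decay.

    Update rule: g <- grad + wd * w; buf <- m * buf + g; w <- w - lr * buf.
    """

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buffers: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                buf = self._buffers.get(id(p))
                if buf is None:
                    buf = np.zeros_like(p.data)
                    self._buffers[id(p)] = buf
                buf *= self.momentum
                buf += g
                g = buf
            p.data = p.data - self.lr * g
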