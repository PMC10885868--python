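"""Minimal reverse-mode automatic differentiation and neural-network layers.

Everything operates on float64 numpy arrays through a small :class:`Tensor`
graph.  The surface intentionally mirrors the conventional deep-learning
vocabulary (``Linear``, ``Conv2d``, ``BatchNorm``, ``Adam``, ``detach`` as the
stop-gradient operator) so that the two-branch privileged-information network
built on top of it reads like its published description.  Gradients of every
primitive are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import copy
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "constant",
    "concat",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "ReLU",
    "Sequential",
    "MaxPool2d",
    "GlobalAvgPool",
    "Adam",
    "cross_entropy",
    "softmax",
    "numerical_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph mechanics ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        """Stop-gradient: same values, no backward path."""
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1))
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def softplus(self):
        # log(1 + exp(x)), numerically stable
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(
            g / (1.0 + np.exp(-self.data)))
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bwd
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class with parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, (BatchNorm1d, BatchNorm2d)):
                state.append(m.running_mean.copy())
                state.append(m.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        state = list(state)
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p.data = s.copy()
        rest = state[len(params):]
        i = 0
        for m in self.modules():
            if isinstance(m, (BatchNorm1d, BatchNorm2d)):
                m.running_mean = rest[i].copy()
                m.running_var = rest[i + 1].copy()
                i += 2

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state_dict())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_he_normal(rng, (out_features, in_features),
                                           in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose((1, 0)) + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _BatchNormBase(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _normalize(self, x: Tensor, axes: tuple[int, ...],
                   shape: tuple[int, ...]) -> Tensor:
        if self.training:
            if x.data.shape[0] < 2 and x.ndim == 2:
                raise ValueError(
                    "batch normalization requires a batch of at least 2 in "
                    "training mode")
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            n = int(np.prod([x.data.shape[a] for a in axes]))
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbias * var.data.reshape(-1))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = constant(self.running_mean.reshape(shape))
            var = constant(self.running_var.reshape(shape))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        gamma = self.gamma.reshape(*shape)
        beta = self.beta.reshape(*shape)
        return xhat * gamma + beta


class BatchNorm1d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0,), (1, self.num_features))


class BatchNorm2d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0, 2, 3), (1, self.num_features, 1, 1))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int,
            pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw),
                                                       axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, oh, ow, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow,
                                                       c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


class Conv2d(Module):
    """2-D convolution via im2col with an explicit col2im backward."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_normal(rng, (out_channels, fan_in), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        cols, oh, ow = _im2col(x.data, k, k, s, p)
        out2d = cols @ self.weight.data.T
        if self.bias is not None:
            out2d = out2d + self.bias.data
        out_data = out2d.reshape(n, oh, ow, self.out_channels)
        out_data = out_data.transpose(0, 3, 1, 2)
        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = Tensor(out_data, parents=parents)

        def bwd(g):
            g2d = g.transpose(0, 2, 3, 1).reshape(n * oh * ow,
                                                  self.out_channels)
            self.weight._accumulate(g2d.T @ cols)
            if self.bias is not None:
                self.bias._accumulate(g2d.sum(axis=0))
            if x.requires_grad:
                dcols = g2d @ self.weight.data
                dcols = dcols.reshape(n, oh, ow, c, k, k)
                hp, wp = h + 2 * p, w + 2 * p
                dxp = np.zeros((n, c, hp, wp))
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                dx = dxp[:, :, p:hp - p, p:wp - p] if p else dxp
                x._accumulate(dx)
        out._backward = bwd
        return out


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = x.data
        if p:
            xp = np.pad(xp, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out_data = windows.max(axis=(-2, -1))
        out = Tensor(out_data, parents=(x,))
        oh, ow = out_data.shape[2], out_data.shape[3]

        def bwd(g):
            mask = windows == out_data[..., None, None]
            mask = mask / mask.sum(axis=(-2, -1), keepdims=True)
            contrib = mask * g[..., None, None]
            hp, wp = h + 2 * p, w + 2 * p
            dxp = np.zeros((n, c, hp, wp))
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                        contrib[:, :, :, :, i, j]
            dx = dxp[:, :, p:hp - p, p:wp - p] if p else dxp
            x._accumulate(dx)
        out._backward = bwd
        return out


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# Losses and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class targets against raw logits."""
    targets = np.asarray(targets, dtype=int)
    n, k = logits.shape
    shift = constant(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log() + shift
    onehot = np.zeros((n, k))
    onehot[np.arange(n), targets] = 1.0
    picked = (logits * constant(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


class Adam:
    """Adam with per-group learning rates (default moment parameters)."""

    def __init__(self, param_groups: Sequence[tuple[Sequence[Parameter], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = [(list(params), float(lr)) for params, lr in param_groups]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(p): np.zeros_like(p.data)
                  for params, _ in self.groups for p in params}
        self.v = {id(p): np.zeros_like(p.data)
                  for params, _ in self.groups for p in params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for params, lr in self.groups:
            if lr == 0.0:
                continue
            for p in params:
                if p.grad is None:
                    continue
                m = self.m[id(p)] = b1 * self.m[id(p)] + (1 - b1) * p.grad
                v = self.v[id(p)] = b2 * self.v[id(p)] + (1 - b2) * p.grad ** 2
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.grad = None


def numerical_grad(f: Callable[[], Tensor], param: Parameter,
                   eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``param``."""
    grad = np.zeros_like(param.data)
    flat = param.data.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(f().data)
        flat[i] = orig - eps
        lo = float(f().data)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad
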