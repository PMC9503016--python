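"""Neural-network building blocks on top of the autograd engine.

Convolutions use an im2col formulation (``sliding_window_view`` + matmul) so
the forward pass stays inside numpy's BLAS; the backward pass scatters column
gradients back with ``np.add.at``.  Layers hold their parameters as
:class:`~histoseg.nn.autograd.Tensor` leaves with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Conv2d", "Linear", "avg_pool2d", "global_avg_pool", "Adam",
           "Module", "he_uniform"]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def _collect_state(self, prefix: str, state: dict) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                value._collect_state(key + ".", state)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", state)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_refs("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)}")
        for key, tensor in own.items():
            tensor.data = np.asarray(state[key], dtype=np.float64).copy()

    def _collect_refs(self, prefix: str, refs: dict) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                refs[key] = value
            elif isinstance(value, Module):
                value._collect_refs(key + ".", refs)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_refs(f"{key}.{i}.", refs)


def _im2col(x: np.ndarray, kh: int, kw: int,
            stride: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]          # (n, c, oh, ow, kh, kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(gcols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int,
            stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    gx = np.zeros(x_shape)
    g = gcols.reshape(n, oh, ow, c, kh, kw)
    for dy in range(kh):
        for dx in range(kw):
            gx[:, :, dy:dy + oh * stride:stride,
               dx:dx + ow * stride:stride] += g[:, :, :, :, dy, dx].transpose(
                   0, 3, 1, 2)
    return gx


class Conv2d(Module):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, *,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            he_uniform(rng, (out_channels, in_channels, kernel_size,
                             kernel_size), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, oh, ow = _im2col(xd, k, k, s)          # (n, L, ckk)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out_data = (cols @ wmat.T + self.bias.data).transpose(0, 2, 1)
        out_data = out_data.reshape(xd.shape[0], self.out_channels, oh, ow)

        conv = self
        x_shape = xd.shape

        def backward(g):
            n = g.shape[0]
            gmat = g.reshape(n, conv.out_channels, -1).transpose(0, 2, 1)
            gw = np.einsum("nlf,nlc->fc", gmat, cols).reshape(
                conv.weight.data.shape)
            gb = gmat.sum(axis=(0, 1))
            gcols = gmat @ wmat                       # (n, L, ckk)
            gx = _col2im(
                gcols.reshape(n, oh, ow, conv.in_channels, k, k),
                x_shape, k, k, s)
            if p:
                gx = gx[:, :, p:-p, p:-p]
            return (gx, gw, gb)

        out = Tensor(out_data)
        if x.requires_grad or self.weight.requires_grad:
            out.requires_grad = True
            out._parents = (x, self.weight, self.bias)
            out._backward = backward
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        self.weight = Tensor(
            he_uniform(rng, (in_features, out_features), in_features),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling; spatial dims must be divisible."""
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {h}x{w} not divisible by {factor}")
    out = x.reshape(n, c, h // factor, factor, w // factor, factor)
    return out.mean(axis=5).mean(axis=3)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=3).mean(axis=2)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
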