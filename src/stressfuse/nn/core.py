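"""Layers, losses, and the Adam optimizer (numpy, explicit backprop).

Array layouts: 2D feature maps are (N, C, H, W); 3D (video) feature maps
are (N, C, T, H, W).  Convolutions use im2col/col2im with 'same' padding
by default.  Every parameterized layer draws its initial weights from its
own generator seeded by ``(master_seed, crc32(layer_name))``, so adding
or removing one layer (e.g. the attention module in an ablation) leaves
every other layer's initialization untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidConfiguration

__all__ = [
    "Parameter",
    "Layer",
    "layer_rng",
    "uniform_init",
    "Dense",
    "ReLU",
    "Conv2d",
    "Conv3d",
    "AvgPool2d",
    "AvgPool3d",
    "GlobalAvgPool",
    "Downsample",
    "Sequential",
    "Residual",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


@dataclass
class Parameter:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


def layer_rng(seed: int, name: str) -> np.random.Generator:
    """Stable per-layer generator: independent of construction order."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot-style uniform draw, U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class Layer:
    """Base layer: forward caches whatever backward needs."""

    name: str = ""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, seed: int, name: str):
        self.name = name
        rng = layer_rng(seed, name)
        self.W = Parameter(f"{name}.W", uniform_init(rng, (n_out, n_in), n_in, n_out))
        self.b = Parameter(f"{name}.b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


def _pad_same(k: int) -> int:
    if k % 2 != 1:
        raise InvalidConfiguration(f"'same' padding needs an odd kernel, got {k}")
    return k // 2


class Conv2d(Layer):
    """2D convolution (cross-correlation) with 'same' padding.

    Output spatial size is ``(dim + 2*pad - k) // stride + 1``; with the
    default stride of 1 the map size is preserved.
    """

    def __init__(self, c_in: int, c_out: int, k: int, seed: int, name: str, stride: int = 1):
        self.name = name
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = _pad_same(k)
        rng = layer_rng(seed, name)
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        self.W = Parameter(f"{name}.W", uniform_init(rng, (c_out, c_in, k, k), fan_in, fan_out))
        self.b = Parameter(f"{name}.b", np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        oh, ow = win.shape[2], win.shape[3]
        # (n, c, oh, ow, k, k) -> (n, c*k*k, oh*ow)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
        self._cols, self._xshape, self._oshape = cols, x.shape, (oh, ow)
        wmat = self.W.value.reshape(self.c_out, -1)
        out = np.einsum("fk,nkp->nfp", wmat, cols) + self.b.value[None, :, None]
        return out.reshape(n, self.c_out, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = self._xshape
        oh, ow = self._oshape
        p, k, c, s = self.pad, self.k, self.c_in, self.stride
        gmat = grad.reshape(n, self.c_out, oh * ow)
        self.W.grad += np.einsum("nfp,nkp->fk", gmat, self._cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=(0, 2))
        wmat = self.W.value.reshape(self.c_out, -1)
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat).reshape(n, c, k, k, oh, ow)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class Conv3d(Layer):
    """3D convolution over (T, H, W), stride 1, 'same' padding.

    Kernel may be a single int (cubic) or a (kt, kh, kw) triple, which is
    what inception-style branches with mixed kernel sizes use.
    """

    def __init__(self, c_in: int, c_out: int, k: int | tuple[int, int, int], seed: int, name: str):
        self.name = name
        kt, kh, kw = (k, k, k) if isinstance(k, int) else k
        self.c_in, self.c_out = c_in, c_out
        self.kt, self.kh, self.kw = kt, kh, kw
        self.pt, self.ph, self.pw = _pad_same(kt), _pad_same(kh), _pad_same(kw)
        rng = layer_rng(seed, name)
        fan_in = c_in * kt * kh * kw
        fan_out = c_out * kt * kh * kw
        self.W = Parameter(
            f"{name}.W", uniform_init(rng, (c_out, c_in, kt, kh, kw), fan_in, fan_out)
        )
        self.b = Parameter(f"{name}.b", np.zeros(c_out))
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        kt, kh, kw = self.kt, self.kh, self.kw
        xp = np.pad(
            x, ((0, 0), (0, 0), (self.pt, self.pt), (self.ph, self.ph), (self.pw, self.pw))
        )
        win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
        cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(n, c * kt * kh * kw, t * h * w)
        self._cols, self._xshape = cols, x.shape
        wmat = self.W.value.reshape(self.c_out, -1)
        out = np.einsum("fk,nkp->nfp", wmat, cols) + self.b.value[None, :, None]
        return out.reshape(n, self.c_out, t, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, t, h, w = grad.shape
        c, kt, kh, kw = self.c_in, self.kt, self.kh, self.kw
        gmat = grad.reshape(n, self.c_out, t * h * w)
        self.W.grad += np.einsum("nfp,nkp->fk", gmat, self._cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=(0, 2))
        wmat = self.W.value.reshape(self.c_out, -1)
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat).reshape(n, c, kt, kh, kw, t, h, w)
        dxp = np.zeros(
            (n, c, t + 2 * self.pt, h + 2 * self.ph, w + 2 * self.pw)
        )
        for i in range(kt):
            for j in range(kh):
                for l in range(kw):
                    dxp[:, :, i : i + t, j : j + h, l : l + w] += dcols[:, :, i, j, l]
        return dxp[
            :, :, self.pt : self.pt + t, self.ph : self.ph + h, self.pw : self.pw + w
        ]

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class AvgPool2d(Layer):
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int, name: str = "avgpool2d"):
        self.name = name
        self.f = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        f = self.f
        if h % f or w % f:
            raise InvalidConfiguration(f"spatial dims {(h, w)} not divisible by {f}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.f
        g = grad / (f * f)
        return np.repeat(np.repeat(g, f, axis=2), f, axis=3)


class AvgPool3d(Layer):
    """Non-overlapping average pooling by (ft, fh, fw) factors."""

    def __init__(self, factor: tuple[int, int, int], name: str = "avgpool3d"):
        self.name = name
        self.ft, self.fh, self.fw = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        ft, fh, fw = self.ft, self.fh, self.fw
        if t % ft or h % fh or w % fw:
            raise InvalidConfiguration(f"dims {(t, h, w)} not divisible by {(ft, fh, fw)}")
        return x.reshape(n, c, t // ft, ft, h // fh, fh, w // fw, fw).mean(axis=(3, 5, 7))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ft, fh, fw = self.ft, self.fh, self.fw
        g = grad / (ft * fh * fw)
        g = np.repeat(g, ft, axis=2)
        g = np.repeat(g, fh, axis=3)
        return np.repeat(g, fw, axis=4)


class GlobalAvgPool(Layer):
    """Mean over all axes after the channel axis: (N, C, ...) -> (N, C)."""

    def __init__(self, name: str = "gap"):
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._in_shape
        scale = int(np.prod(shape[2:]))
        expand = (slice(None), slice(None)) + (None,) * (len(shape) - 2)
        return np.broadcast_to(grad[expand] / scale, shape).copy()


class Downsample(Layer):
    """Deterministic, non-trainable input reduction stem.

    Temporal stride subsampling plus block-average spatial pooling bring
    full-resolution clips/images down to the tiny backbone's working size.
    No trainable parameters precede it, so backward is never required.
    """

    def __init__(self, spatial: int, t_stride: int = 1, name: str = "downsample"):
        self.name = name
        self.spatial = spatial
        self.t_stride = t_stride

    def _pool_hw(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[-2:]
        s = self.spatial
        if h == s and w == s:
            return x
        if h % s == 0 and w % s == 0:
            fh, fw = h // s, w // s
            shape = x.shape[:-2] + (s, fh, s, fw)
            return x.reshape(shape).mean(axis=(-3, -1))
        # fall back to area-style interpolation on awkward sizes
        from skimage.transform import resize as _resize

        flat = x.reshape(-1, h, w)
        out = np.stack(
            [_resize(f, (s, s), order=1, mode="edge", anti_aliasing=False) for f in flat]
        )
        return out.reshape(x.shape[:-2] + (s, s))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 5 and self.t_stride > 1:
            x = x[:, :, :: self.t_stride]
        return self._pool_hw(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # first layer of every backbone: no parameters below it need the
        # gradient, so stop the chain here
        return grad


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "seq"):
        self.name = name
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class Residual(Layer):
    """y = F(x) + x followed by ReLU; F must preserve the input shape."""

    def __init__(self, branch: Layer, name: str = "residual"):
        self.name = name
        self.branch = branch
        self._relu = ReLU(f"{name}.relu")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self._relu.forward(self.branch.forward(x, train=train) + x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self._relu.backward(grad)
        return self.branch.backward(g) + g

    def parameters(self) -> list[Parameter]:
        return self.branch.parameters()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if lr < 0:
            raise InvalidConfiguration("learning rate must be nonnegative")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
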