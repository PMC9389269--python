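"""Temporal Attention Module (TAM): a temporal squeeze-excitation gate.

Not every frame of a facial-expression clip is equally informative, so a
per-frame gate reweights the temporal axis of an early 3D feature map.
For a feature map ``u`` with T frames of shape C x H x W:

* squeeze:  ``z_t = mean over (C, H, W) of u_t``          (z in R^T)
* excite:   ``S = sigmoid(W2 @ relu(W1 @ z))``            (S in (0,1)^T)
* scale:    ``out_t = S_t * u_t``

``W1`` is (T/r x T) and ``W2`` is (T x T/r) with reduction ratio ``r``;
non-integer T/r rounds to ``max(1, round(T/r))``.  Because every gate is
a sigmoid output, the module is a strict per-frame contraction.

The functional forms below operate on a single clip laid out (T, C, H, W);
:class:`TemporalAttention` is the trainable batched layer, laid out
(N, C, T, H, W) to match the convolution stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidConfiguration
from .core import Layer, Parameter, layer_rng, uniform_init

__all__ = [
    "TAMParams",
    "AttentionMap",
    "tam_hidden_size",
    "tam_squeeze",
    "tam_excite",
    "tam_scale",
    "tam_forward",
    "TemporalAttention",
]

DEFAULT_REDUCTION = 4


def tam_hidden_size(T: int, r: int) -> int:
    if r < 1:
        raise InvalidConfiguration(f"reduction ratio must be >= 1, got {r}")
    return max(1, round(T / r))


@dataclass(frozen=True)
class TAMParams:
    """Weights of the two gate layers; W1 is (T/r, T), W2 is (T, T/r)."""

    W1: np.ndarray
    W2: np.ndarray

    @classmethod
    def init(cls, T: int, r: int = DEFAULT_REDUCTION, seed: int = 0, name: str = "tam") -> "TAMParams":
        hidden = tam_hidden_size(T, r)
        rng = layer_rng(seed, name)
        return cls(
            W1=uniform_init(rng, (hidden, T), T, hidden),
            W2=uniform_init(rng, (T, hidden), hidden, T),
        )

    @property
    def T(self) -> int:
        return self.W1.shape[1]

    def __post_init__(self) -> None:
        if self.W1.shape[0] != self.W2.shape[1] or self.W1.shape[1] != self.W2.shape[0]:
            raise InvalidConfiguration(
                f"inconsistent gate shapes W1 {self.W1.shape}, W2 {self.W2.shape}"
            )


@dataclass(frozen=True)
class AttentionMap:
    """Per-frame gates, each strictly inside (0, 1)."""

    S: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def tam_squeeze(u: np.ndarray) -> np.ndarray:
    """z_t = mean of frame t over channel and space; u is (T, C, H, W)."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 4 or u.size == 0:
        raise InvalidConfiguration(f"expected nonempty (T, C, H, W) map, got shape {u.shape}")
    return u.mean(axis=(1, 2, 3))


def tam_excite(z: np.ndarray, params: TAMParams) -> AttentionMap:
    """S = sigmoid(W2 @ relu(W1 @ z))."""
    z = np.asarray(z, dtype=float)
    if z.shape != (params.T,):
        raise InvalidConfiguration(
            f"z has shape {z.shape}, gate expects ({params.T},)"
        )
    h = np.maximum(params.W1 @ z, 0.0)
    return AttentionMap(S=_sigmoid(params.W2 @ h))


def tam_scale(u: np.ndarray, S: AttentionMap | np.ndarray) -> np.ndarray:
    """out_t = S_t * u_t, elementwise over the frame."""
    s = S.S if isinstance(S, AttentionMap) else np.asarray(S, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.shape[0] != u.shape[0]:
        raise InvalidConfiguration(
            f"attention length {s.shape[0]} != temporal length {u.shape[0]}"
        )
    return u * s[:, None, None, None]


def tam_forward(u: np.ndarray, params: TAMParams) -> np.ndarray:
    """Squeeze, excite, scale in one call (single clip, (T, C, H, W))."""
    return tam_scale(u, tam_excite(tam_squeeze(u), params))


class TemporalAttention(Layer):
    """Trainable batched TAM operating on (N, C, T, H, W) feature maps."""

    def __init__(self, T: int, r: int = DEFAULT_REDUCTION, seed: int = 0, name: str = "tam"):
        self.name = name
        self.T = T
        self.r = r
        hidden = tam_hidden_size(T, r)
        rng = layer_rng(seed, name)
        self.W1 = Parameter(f"{name}.W1", uniform_init(rng, (hidden, T), T, hidden))
        self.W2 = Parameter(f"{name}.W2", uniform_init(rng, (T, hidden), hidden, T))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        if t != self.T:
            raise InvalidConfiguration(f"TAM built for T={self.T}, got T={t}")
        z = x.mean(axis=(1, 3, 4))  # (N, T)
        a = z @ self.W1.value.T  # (N, hidden)
        hrelu = np.maximum(a, 0.0)
        s = _sigmoid(hrelu @ self.W2.value.T)  # (N, T)
        self._cache = (x, z, a, hrelu, s)
        return x * s[:, None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, a, hrelu, s = self._cache
        n, c, t, h, w = x.shape
        chw = c * h * w
        dx = grad * s[:, None, :, None, None]
        ds = np.einsum("ncthw,ncthw->nt", grad, x)
        dlogit = ds * s * (1.0 - s)  # sigmoid derivative
        self.W2.grad += dlogit.T @ hrelu
        dh = dlogit @ self.W2.value
        da = np.where(a > 0, dh, 0.0)
        self.W1.grad += da.T @ z
        dz = da @ self.W1.value  # (N, T)
        dx += dz[:, None, :, None, None] / chw
        return dx

    def parameters(self) -> list[Parameter]:
        return [self.W1, self.W2]
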