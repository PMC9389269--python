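"""Backbone builders: residual 2D image net and inception 3D video net.

Each backbone comes in two variants.  ``tiny`` is the desk-scale default:
a deterministic downsampling stem brings the full-resolution input
(307x230-class images, 64-frame 224x224 clips) down to a small working
size, followed by a shallow stack (two residual stages for images, two
inception modules for video) that one CPU trains in minutes.  ``full``
reproduces the published stage layouts (the 3+4+6+3 bottleneck plan of
the 50-layer residual net; the 9-inception-module inflated-inception
plan) and exists for structural fidelity and forward passes, not for
desk-scale training.

The video net optionally carries the temporal attention module right
after its first convolution+pooling stage, so the gate acts on the
proportion of temporal information the initial layer passes upward.
Both variants end in a 3-way fully connected layer whose softmax is the
(calm, control, experimental) posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ..errors import InvalidConfiguration
from .core import (
    AvgPool2d,
    AvgPool3d,
    Conv2d,
    Conv3d,
    Dense,
    Downsample,
    GlobalAvgPool,
    Layer,
    Parameter,
    ReLU,
    Residual,
    Sequential,
)
from .tam import DEFAULT_REDUCTION, TemporalAttention

__all__ = [
    "BackboneConfig",
    "Model",
    "build_image_net",
    "build_video_net",
    "count_parameters",
    "parameter_shapes",
    "RESNET50_STAGES",
    "I3D_INCEPTION_PLAN",
]

#: Published 50-layer residual plan: (bottleneck width, output width, blocks, stride).
RESNET50_STAGES = [
    (64, 256, 3, 1),
    (128, 512, 4, 2),
    (256, 1024, 6, 2),
    (512, 2048, 3, 2),
]

#: Published inflated-inception plan: branch widths
#: (b1, (b2_reduce, b2), (b3_reduce, b3), b4_pool_proj) per module.
I3D_INCEPTION_PLAN = [
    (64, (96, 128), (16, 32), 32),     # 3b
    (128, (128, 192), (32, 96), 64),   # 3c
    (192, (96, 208), (16, 48), 64),    # 4b
    (160, (112, 224), (24, 64), 64),   # 4c
    (128, (128, 256), (24, 64), 64),   # 4d
    (112, (144, 288), (32, 64), 64),   # 4e
    (256, (160, 320), (32, 128), 128), # 4f
    (256, (160, 320), (32, 128), 128), # 5b
    (384, (192, 384), (48, 128), 128), # 5c
]

TINY_INCEPTION_PLAN = [
    (4, (4, 6), (2, 3), 3),    # out 16
    (8, (6, 10), (3, 4), 2),   # out 24
]


@dataclass(frozen=True)
class BackboneConfig:
    """Shared configuration for both backbones.

    ``clip_len``/``t_stride`` only affect the video net: the stem keeps
    every ``t_stride``-th frame, so the attention module sees
    ``clip_len // t_stride`` frames.
    """

    variant: str = "tiny"
    n_classes: int = 3
    seed: int = 0
    tam: bool = True
    reduction: int = DEFAULT_REDUCTION
    clip_len: int = 64
    t_stride: int = 4
    tiny_spatial: int = 32
    tiny_video_spatial: int = 16

    def __post_init__(self) -> None:
        if self.variant not in ("tiny", "full"):
            raise InvalidConfiguration(f"unknown variant {self.variant!r}")
        if self.n_classes < 2:
            raise InvalidConfiguration("need at least 2 classes")
        if self.clip_len % self.t_stride:
            raise InvalidConfiguration("clip_len must be divisible by t_stride")

    @property
    def tam_T(self) -> int:
        return self.clip_len // self.t_stride


class Model(Sequential):
    """A backbone plus bookkeeping used by the training loop."""

    def __init__(self, layers: list[Layer], config: BackboneConfig, kind: str):
        super().__init__(layers, name=f"{kind}-{config.variant}")
        self.config = config
        self.kind = kind

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]


class _SmoothPool3d(Layer):
    """3x3x3 stride-1 average pool (same padding) for the inception pool
    branch; zero-padded, hence self-adjoint, so backward is the same filter."""

    SIZE = (1, 1, 1, 3, 3)

    def __init__(self, name: str = "poolbranch"):
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return ndimage.uniform_filter(x, size=self.SIZE, mode="constant")

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(grad, size=self.SIZE, mode="constant")


class _Inception3d(Layer):
    """Four parallel branches concatenated on the channel axis:
    1x1x1 / 1x1x1->3x3x3 / 1x1x1->3x3x3 / pool->1x1x1."""

    def __init__(self, c_in: int, plan: tuple, seed: int, name: str):
        b1, (b2r, b2), (b3r, b3), b4 = plan
        self.name = name
        self.branches: list[Layer] = [
            Conv3d(c_in, b1, 1, seed, f"{name}.b1"),
            Sequential(
                [
                    Conv3d(c_in, b2r, 1, seed, f"{name}.b2reduce"),
                    ReLU(),
                    Conv3d(b2r, b2, 3, seed, f"{name}.b2conv"),
                ],
                name=f"{name}.b2",
            ),
            Sequential(
                [
                    Conv3d(c_in, b3r, 1, seed, f"{name}.b3reduce"),
                    ReLU(),
                    Conv3d(b3r, b3, 3, seed, f"{name}.b3conv"),
                ],
                name=f"{name}.b3",
            ),
            Sequential(
                [_SmoothPool3d(f"{name}.pool"), Conv3d(c_in, b4, 1, seed, f"{name}.b4proj")],
                name=f"{name}.b4",
            ),
        ]
        self._relu = ReLU(f"{name}.relu")
        self.c_out = b1 + b2 + b3 + b4
        self._splits: list[int] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = [o.shape[1] for o in outs]
        return self._relu.forward(np.concatenate(outs, axis=1), train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self._relu.backward(grad)
        pieces = np.split(grad, np.cumsum(self._splits)[:-1], axis=1)
        return sum(b.backward(g) for b, g in zip(self.branches, pieces))

    def parameters(self) -> list[Parameter]:
        return [p for b in self.branches for p in b.parameters()]


class _Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 residual bottleneck with optional projection."""

    def __init__(self, c_in: int, mid: int, c_out: int, stride: int, seed: int, name: str):
        self.name = name
        self.body = Sequential(
            [
                Conv2d(c_in, mid, 1, seed, f"{name}.conv1"),
                ReLU(),
                Conv2d(mid, mid, 3, seed, f"{name}.conv2", stride=stride),
                ReLU(),
                Conv2d(mid, c_out, 1, seed, f"{name}.conv3"),
            ],
            name=f"{name}.body",
        )
        self.project: Layer | None = None
        if stride != 1 or c_in != c_out:
            self.project = Conv2d(c_in, c_out, 1, seed, f"{name}.proj", stride=stride)
        self._relu = ReLU(f"{name}.relu")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shortcut = self.project.forward(x, train=train) if self.project else x
        return self._relu.forward(self.body.forward(x, train=train) + shortcut, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self._relu.backward(grad)
        dx = self.body.backward(g)
        dx += self.project.backward(g) if self.project else g
        return dx

    def parameters(self) -> list[Parameter]:
        params = self.body.parameters()
        if self.project:
            params += self.project.parameters()
        return params


def _basic_residual(c: int, seed: int, name: str) -> Residual:
    branch = Sequential(
        [Conv2d(c, c, 3, seed, f"{name}.conv1"), ReLU(), Conv2d(c, c, 3, seed, f"{name}.conv2")],
        name=f"{name}.branch",
    )
    return Residual(branch, name=name)


def build_image_net(config: BackboneConfig) -> Model:
    """Residual 2D classifier mapping (N, 3, H, W) images to 3-way logits."""
    seed = config.seed
    if config.variant == "tiny":
        layers: list[Layer] = [
            Downsample(config.tiny_spatial, name="stem"),
            Conv2d(3, 16, 3, seed, "conv1"),
            ReLU(),
            AvgPool2d(2),
            _basic_residual(16, seed, "res1"),
            AvgPool2d(2),
            _basic_residual(16, seed, "res2"),
            GlobalAvgPool(),
            Dense(16, config.n_classes, seed, "fc"),
        ]
        return Model(layers, config, kind="image")
    layers = [
        Conv2d(3, 64, 7, seed, "conv1", stride=2),
        ReLU(),
        AvgPool2d(2, name="pool1"),
    ]
    c_in = 64
    for s, (mid, c_out, blocks, stride) in enumerate(RESNET50_STAGES, start=2):
        for b in range(blocks):
            layers.append(
                _Bottleneck(
                    c_in, mid, c_out, stride if b == 0 else 1, seed, f"stage{s}.block{b}"
                )
            )
            c_in = c_out
    layers += [GlobalAvgPool(), Dense(c_in, config.n_classes, seed, "fc")]
    return Model(layers, config, kind="image")


def build_video_net(config: BackboneConfig, tam: bool | None = None) -> Model:
    """Inception 3D classifier mapping (N, 3, T, H, W) clips to 3-way logits.

    ``tam=False`` removes only the temporal attention module: every other
    layer keeps its name-derived initialization, so the ablation isolates
    the module exactly.
    """
    seed = config.seed
    use_tam = config.tam if tam is None else tam
    if config.variant == "tiny":
        T = config.tam_T
        layers: list[Layer] = [
            Downsample(config.tiny_video_spatial, t_stride=config.t_stride, name="stem"),
            Conv3d(3, 8, 3, seed, "vconv1"),
            ReLU(),
            AvgPool3d((1, 2, 2)),
        ]
        if use_tam:
            layers.append(TemporalAttention(T, r=config.reduction, seed=seed, name="tam"))
        c_in = 8
        for i, plan in enumerate(TINY_INCEPTION_PLAN, start=1):
            block = _Inception3d(c_in, plan, seed, f"inc{i}")
            layers.append(block)
            c_in = block.c_out
            if i == 1:
                layers.append(AvgPool3d((2, 2, 2)))
        layers += [GlobalAvgPool(), Dense(c_in, config.n_classes, seed, "fc")]
        return Model(layers, config, kind="video")
    T = config.tam_T
    layers = [
        Downsample(64, t_stride=config.t_stride, name="stem"),
        Conv3d(3, 64, 7, seed, "vconv1"),
        ReLU(),
        AvgPool3d((1, 2, 2), name="pool1"),
    ]
    if use_tam:
        layers.append(TemporalAttention(T, r=config.reduction, seed=seed, name="tam"))
    layers += [
        Conv3d(64, 64, 1, seed, "vconv2"),
        ReLU(),
        Conv3d(64, 192, 3, seed, "vconv3"),
        ReLU(),
        AvgPool3d((1, 2, 2), name="pool2"),
    ]
    c_in = 192
    for i, plan in enumerate(I3D_INCEPTION_PLAN):
        block = _Inception3d(c_in, plan, seed, f"mixed{i}")
        layers.append(block)
        c_in = block.c_out
        if i in (1, 6):  # pool between the 2 / 5 / 2 module groups
            layers.append(AvgPool3d((2, 2, 2), name=f"pool{3 + (i > 1)}"))
    layers += [GlobalAvgPool(), Dense(c_in, config.n_classes, seed, "fc")]
    return Model(layers, config, kind="video")


def count_parameters(model: Model) -> int:
    return int(sum(p.value.size for p in model.parameters()))


def parameter_shapes(model: Model) -> dict[str, tuple[int, ...]]:
    return {p.name: p.value.shape for p in model.parameters()}


def clone_config(config: BackboneConfig, **kwargs) -> BackboneConfig:
    return replace(config, **kwargs)
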