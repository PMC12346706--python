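"""Limited-receptive-field backbone: a bag-of-local-features extractor.

The full configuration follows the BagNet-33 construction: a ResNet-50
bottleneck topology in which the stem is a 1x1 then a 3x3 convolution
and each stage's *first* bottleneck carries the stage's only 3x3
convolution (all other spatial convolutions are 1x1), with no padding
anywhere. The composed receptive field is then exactly 33x33 pixels and
the composed stride 8, so a 225x225 image maps to a 25x25x2048 grid
where cell (i, j) depends only on input rows [8i, 8i+32] and columns
[8j, 8j+32]. Residual shortcuts are cropped top-left on spatial
mismatch, which keeps every cell's support anchored at (8i, 8j).

A "tiny" configuration (57x57 input, 9x9 patch, stride 8, 64 channels)
uses a plain no-padding convolution stack with the same locality
guarantees, so every downstream module is testable on a CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    no_grad,
    relu,
)

__all__ = [
    "BackboneConfig",
    "TINY_CONFIG",
    "SMALL_CONFIG",
    "FULL_CONFIG",
    "build_backbone",
    "extract_features",
    "receptive_field_probe",
    "plain_recipe_geometry",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Geometry and width of the local-feature extractor.

    ``topology`` is either ``"bagnet50"`` (the bottleneck table above;
    requires patch_size 33, stride 8) or ``"plain"`` (an explicit
    ``recipe`` of (kernel, stride, channels) convolution layers).
    """

    input_size: int = 225
    patch_size: int = 33
    stride: int = 8
    channels: int = 2048
    topology: str = "bagnet50"
    recipe: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self):
        if (self.input_size - self.patch_size) % self.stride != 0:
            raise ValueError(
                f"(input_size - patch_size) = {self.input_size - self.patch_size} "
                f"must be divisible by stride {self.stride}"
            )
        if self.topology == "bagnet50":
            if (self.patch_size, self.stride) != (33, 8):
                raise ValueError("bagnet50 topology realizes patch 33 / stride 8 only")
        elif self.topology == "plain":
            rf, st = plain_recipe_geometry(self.recipe)
            if rf != self.patch_size or st != self.stride:
                raise ValueError(
                    f"recipe realizes receptive field {rf} / stride {st}, "
                    f"config declares {self.patch_size} / {self.stride}"
                )
            if self.recipe[-1][2] != self.channels:
                raise ValueError("last recipe layer must emit config.channels")
        else:
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def grid_size(self) -> int:
        return (self.input_size - self.patch_size) // self.stride + 1


def plain_recipe_geometry(recipe) -> tuple[int, int]:
    """Analytic (receptive field, composed stride) of a conv stack.

    RF grows by (k-1) * jump at each layer; the jump is the product of
    the strides applied so far.
    """
    if not recipe:
        raise ValueError("empty recipe")
    rf, jump = 1, 1
    for k, s, _c in recipe:
        rf += (k - 1) * jump
        jump *= s
    return rf, jump


_TINY_RECIPE = ((1, 1, 16), (3, 1, 32), (3, 2, 48), (3, 2, 64), (1, 2, 64))

TINY_CONFIG = BackboneConfig(
    input_size=57, patch_size=9, stride=8, channels=64,
    topology="plain", recipe=_TINY_RECIPE,
)
# same stack on a 105-px canvas: a 13x13 grid, dense enough for
# window-masking analyses at the k used at full scale
SMALL_CONFIG = BackboneConfig(
    input_size=105, patch_size=9, stride=8, channels=64,
    topology="plain", recipe=_TINY_RECIPE,
)
FULL_CONFIG = BackboneConfig()


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, k, stride, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class _Bottleneck(Module):
    """ResNet bottleneck with an un-padded 3x3 or 1x1 middle conv.

    When the main path shrinks or strides the spatial grid, the shortcut
    is a strided 1x1 conv + BN and is cropped top-left to the main
    path's size.
    """

    expansion = 4

    def __init__(self, inplanes, planes, stride, kernel, rng):
        super().__init__()
        out = planes * self.expansion
        self.conv1 = Conv2d(inplanes, planes, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, kernel, rng, stride=stride, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(out)
        if stride != 1 or inplanes != out:
            self.down_conv = Conv2d(inplanes, out, 1, rng, stride=stride, bias=False)
            self.down_bn = BatchNorm2d(out)
        else:
            self.down_conv = None

    def forward(self, x):
        out = relu(self.bn1(self.conv1(x)))
        out = relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x))
        else:
            shortcut = x
        dh = shortcut.shape[2] - out.shape[2]
        dw = shortcut.shape[3] - out.shape[3]
        if dh or dw:
            shortcut = shortcut[:, :, : shortcut.shape[2] - dh, : shortcut.shape[3] - dw]
        return relu(out + shortcut)


class Backbone(Module):
    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        if config.topology == "plain":
            layers = []
            cin = 3
            for k, s, c in config.recipe:
                layers.append(_ConvBNReLU(cin, c, k, s, rng))
                cin = c
            self.body = Sequential(*layers)
        else:
            self.stem = Sequential(
                Conv2d(3, 64, 1, rng, bias=False),
                _ConvBNReLU2(64, 64, 3, 1, rng),
            )
            stages = []
            inplanes = 64
            for planes, blocks, stage_stride in (
                (64, 3, 2), (128, 4, 2), (256, 6, 2), (512, 3, 1),
            ):
                stage = [_Bottleneck(inplanes, planes, stage_stride, 3, rng)]
                inplanes = planes * _Bottleneck.expansion
                for _ in range(blocks - 1):
                    stage.append(_Bottleneck(inplanes, planes, 1, 1, rng))
                stages.append(Sequential(*stage))
            self.body = Sequential(self.stem, *stages)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _ConvBNReLU2(_ConvBNReLU):
    """Stem 3x3 conv + BN + ReLU (separate class only for clarity in repr)."""


def build_backbone(config: BackboneConfig, seed: int = 0) -> Backbone:
    """Instantiate a backbone with He-normal random initialization."""
    return Backbone(config, np.random.default_rng(seed))


def _validate_batch(images: np.ndarray, config: BackboneConfig) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got shape {images.shape}")
    if images.shape[1] != config.input_size or images.shape[2] != config.input_size:
        raise ValueError(
            f"backbone expects {config.input_size}x{config.input_size} inputs, "
            f"got {images.shape[1]}x{images.shape[2]} (no silent resizing)"
        )
    return images


def extract_features(backbone: Backbone, images: np.ndarray) -> np.ndarray:
    """Deterministic feature grids for a batch of images.

    Input (N, H, W, 3) in [0, 1]; output (N, grid, grid, channels). Runs
    in eval mode (frozen normalization statistics), so the strict
    per-patch locality of the architecture holds exactly.
    """
    images = _validate_batch(images, backbone.config)
    was_training = backbone.training
    backbone.eval()
    try:
        with no_grad():
            x = Tensor(images.transpose(0, 3, 1, 2).astype(np.float32))
            out = backbone(x)
    finally:
        backbone.train(was_training)
    return out.data.transpose(0, 2, 3, 1)


def receptive_field_probe(
    backbone: Backbone,
    cell: tuple[int, int],
    n_probes: int = 2,
    seed: int = 0,
    dtype=np.float64,
) -> tuple[int, int, int, int]:
    """Measured input support of one output cell, as (top, left, height, width).

    Backpropagates the sum of that cell's channels to the input for
    ``n_probes`` random images and returns the bounding box of the union
    of nonzero gradient support. Run in eval mode so normalization does
    not couple positions.
    """
    config = backbone.config
    i, j = cell
    rng = np.random.default_rng(seed)
    was_training = backbone.training
    backbone.eval()
    support = np.zeros((config.input_size, config.input_size), dtype=bool)
    try:
        for _ in range(n_probes):
            img = rng.random((1, 3, config.input_size, config.input_size)).astype(dtype)
            x = Tensor(img, requires_grad=True)
            out = backbone(x)
            out[0, :, i, j].sum().backward()
            support |= (np.abs(x.grad).sum(axis=(0, 1)) != 0)
    finally:
        backbone.train(was_training)
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    if rows.size == 0:
        return (0, 0, 0, 0)
    return (
        int(rows[0]),
        int(cols[0]),
        int(rows[-1] - rows[0] + 1),
        int(cols[-1] - cols[0] + 1),
    )
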