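"""Divergers, non-rigid-reconstruction decoders, gates and the classifier.

The backbone's feature grid X is split by two independent 1x1-conv
divergers into a color-texture-biased stream X_CTI and an edge-biased
stream X_EI. During training each stream parameterizes a diagonal
Gaussian (mu, sigma) from which a sample z = mu + sigma * eps is drawn
with the reparameterization trick; the CTI sample is a 354-vector
matched against the handcrafted descriptor, while the EI sample is a
grid-shaped field that a bottleneck + transposed convolution (kernel =
patch size, stride = grid stride) decodes back to an input-sized edge
map in strict spatial correspondence with the backbone's downsampling.
Sigma branches output log-sigma and are exponentiated, which is what
makes sigma strictly positive.

For classification, each stream passes through a sigmoid spatial gate
(1x1 convs -> scalar per cell), the gated streams are concatenated,
globally average pooled, and a single affine FC layer produces logits.
Because GAP and an affine map commute, the image logit is exactly the
mean of per-cell logits — the property the heatmaps exploit.

At inference the decoders are dropped; only divergers, gates and the
classifier run.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .autodiff import (
    Conv2d,
    ConvTranspose2d,
    Linear,
    Module,
    Tensor,
    concat,
    conv_transpose2d,
    exp,
    global_avg_pool,
    relu,
    sigmoid,
)
from .backbone import Backbone, BackboneConfig, FULL_CONFIG, SMALL_CONFIG, TINY_CONFIG, build_backbone
from .features import DESCRIPTOR_LENGTH

__all__ = [
    "ModelConfig",
    "TINY_MODEL_CONFIG",
    "SMALL_MODEL_CONFIG",
    "FULL_MODEL_CONFIG",
    "GaussianFeatureField",
    "ModelOutputs",
    "EdgeTextureBagModel",
    "build_model",
    "reparameterized_sample",
]


@dataclass(frozen=True)
class ModelConfig:
    """Widths of the heads around a backbone configuration.

    Defaults mirror the full-scale model (2048-channel grid): 128-wide
    decoder bottlenecks, 64-wide gate bottlenecks, 7 output classes.
    """

    backbone: BackboneConfig = dataclass_field(default_factory=BackboneConfig)
    n_classes: int = 7
    decoder_hidden: int = 128
    gate_hidden: int = 64
    cti_dim: int = DESCRIPTOR_LENGTH

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


FULL_MODEL_CONFIG = ModelConfig(backbone=FULL_CONFIG)
TINY_MODEL_CONFIG = ModelConfig(
    backbone=TINY_CONFIG, n_classes=3, decoder_hidden=16, gate_hidden=16
)
SMALL_MODEL_CONFIG = ModelConfig(
    backbone=SMALL_CONFIG, n_classes=3, decoder_hidden=16, gate_hidden=16
)


@dataclass
class GaussianFeatureField:
    """A diagonal Gaussian over a feature space: sample z = mu + sigma * eps."""

    mu: Tensor
    sigma: Tensor

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must share a shape")
        if (self.sigma.data <= 0).any():
            raise ValueError("sigma must be strictly positive")


def reparameterized_sample(
    field: GaussianFeatureField,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> Tensor:
    """Differentiable draw z = mu + sigma * eps with eps ~ N(0, 1).

    Pass ``eps`` explicitly to pin the noise (eps = 0 recovers the mean);
    otherwise it is drawn from ``rng``.
    """
    if eps is None:
        if rng is None:
            raise ValueError("provide either rng or eps")
        eps = rng.standard_normal(field.mu.shape)
    eps = np.asarray(eps, dtype=field.mu.dtype)
    return field.mu + field.sigma * Tensor(eps)


class Diverger(Module):
    """One 1x1 convolution, purely affine (no nonlinearity)."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv = Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class _VectorBranch(Module):
    """GAP -> ReLU -> FC (C -> hidden) -> ReLU -> FC (hidden -> out)."""

    def __init__(self, channels, hidden, out, rng):
        super().__init__()
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(relu(global_avg_pool(x)))))


class CTIDecoder(Module):
    """Gaussian over the 354-D descriptor space, from the pooled CTI stream.

    The mu and sigma branches are fully separate parameter sets; the
    sigma branch's raw output is log-sigma.
    """

    def __init__(self, channels, hidden, out_dim, rng):
        super().__init__()
        self.mu_branch = _VectorBranch(channels, hidden, out_dim, rng)
        self.log_sigma_branch = _VectorBranch(channels, hidden, out_dim, rng)

    def forward(self, x: Tensor) -> GaussianFeatureField:
        return GaussianFeatureField(
            mu=self.mu_branch(x), sigma=exp(self.log_sigma_branch(x))
        )


class _CellBranch(Module):
    """ReLU -> 1x1 conv (C -> hidden) -> ReLU -> 1x1 conv (hidden -> C)."""

    def __init__(self, channels, hidden, rng):
        super().__init__()
        self.conv1 = Conv2d(channels, hidden, 1, rng)
        self.conv2 = Conv2d(hidden, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(relu(self.conv1(relu(x))))


class EIDecoder(Module):
    """Per-cell Gaussian over the feature grid plus the upsampling path.

    The upsampler is ReLU -> 1x1 conv (C -> hidden) -> ReLU -> 1x1 conv
    (hidden -> C) -> transposed conv (C -> 1, kernel = patch size,
    stride = grid stride), so a grid of side G maps to (G-1)*stride +
    patch pixels per side — exactly the input size.
    """

    def __init__(self, channels, hidden, patch_size, stride, rng):
        super().__init__()
        self.mu_branch = _CellBranch(channels, hidden, rng)
        self.log_sigma_branch = _CellBranch(channels, hidden, rng)
        self.up_conv1 = Conv2d(channels, hidden, 1, rng)
        self.up_conv2 = Conv2d(hidden, channels, 1, rng)
        self.tconv = ConvTranspose2d(channels, 1, patch_size, rng, stride=stride)

    def forward(self, x: Tensor) -> GaussianFeatureField:
        return GaussianFeatureField(
            mu=self.mu_branch(x), sigma=exp(self.log_sigma_branch(x))
        )

    def upsample(self, z: Tensor) -> Tensor:
        """Decode a grid sample to a single-channel input-sized map."""
        h = self.up_conv2(relu(self.up_conv1(relu(z))))
        return self.tconv(h)


class Gate(Module):
    """Sigmoid spatial attention: 1x1 conv (C -> hidden) -> 1x1 conv (hidden -> 1)."""

    def __init__(self, channels, hidden, rng):
        super().__init__()
        self.conv1 = Conv2d(channels, hidden, 1, rng)
        self.conv2 = Conv2d(hidden, 1, 1, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        weights = sigmoid(self.conv2(self.conv1(x)))  # (N, 1, G, G)
        return x * weights, weights


@dataclass
class ModelOutputs:
    """Everything one forward pass produces (training mode fills all fields)."""

    logits: Tensor
    features: Tensor
    x_cti: Tensor
    x_ei: Tensor
    x_cti_gated: Tensor
    x_ei_gated: Tensor
    gate_cti: Tensor
    gate_ei: Tensor
    cti_field: GaussianFeatureField | None = None
    ei_field: GaussianFeatureField | None = None
    z_cti: Tensor | None = None
    z_ei: Tensor | None = None
    edge_recon: Tensor | None = None


class EdgeTextureBagModel(Module):
    """The full network: backbone, divergers, decoders, gates, classifier."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config.backbone.channels
        self.backbone = Backbone(config.backbone, rng)
        self.diverger_cti = Diverger(c, rng)
        self.diverger_ei = Diverger(c, rng)
        self.cti_decoder = CTIDecoder(c, config.decoder_hidden, config.cti_dim, rng)
        self.ei_decoder = EIDecoder(
            c, config.decoder_hidden, config.backbone.patch_size,
            config.backbone.stride, rng,
        )
        self.gate_cti = Gate(c, config.gate_hidden, rng)
        self.gate_ei = Gate(c, config.gate_hidden, rng)
        self.classifier = Linear(2 * c, config.n_classes, rng)

    def forward(
        self,
        x: Tensor,
        reconstruct: bool = False,
        rng: np.random.Generator | None = None,
        eps_cti: np.ndarray | None = None,
        eps_ei: np.ndarray | None = None,
    ) -> ModelOutputs:
        feats = self.backbone(x)
        x_cti = self.diverger_cti(feats)
        x_ei = self.diverger_ei(feats)
        x_cti_g, a_cti = self.gate_cti(x_cti)
        x_ei_g, a_ei = self.gate_ei(x_ei)
        pooled = concat([global_avg_pool(x_cti_g), global_avg_pool(x_ei_g)], axis=1)
        logits = self.classifier(pooled)
        out = ModelOutputs(
            logits=logits, features=feats, x_cti=x_cti, x_ei=x_ei,
            x_cti_gated=x_cti_g, x_ei_gated=x_ei_g,
            gate_cti=a_cti, gate_ei=a_ei,
        )
        if reconstruct:
            out.cti_field = self.cti_decoder(x_cti)
            out.ei_field = self.ei_decoder(x_ei)
            out.z_cti = reparameterized_sample(out.cti_field, rng=rng, eps=eps_cti)
            out.z_ei = reparameterized_sample(out.ei_field, rng=rng, eps=eps_ei)
            out.edge_recon = self.ei_decoder.upsample(out.z_ei)
        return out


def build_model(config: ModelConfig = TINY_MODEL_CONFIG, seed: int = 0) -> EdgeTextureBagModel:
    return EdgeTextureBagModel(config, np.random.default_rng(seed))
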