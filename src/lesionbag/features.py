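"""Handcrafted reconstruction targets: color-texture descriptor and edge map.

The color-texture descriptor concatenates uniform local-binary-pattern
(LBP, P=8, R=1) histograms computed on six channels — R, G, B and the
BT.601 Y, U, V — giving 6 x 59 = 354 dimensions. The edge map is the
Sobel gradient magnitude of the luma channel, rescaled to [0, 1]. Both
are the targets the model's decoders learn to reconstruct, and both are
what a pre-deep-learning lesion-analysis pipeline would compute:
boundary sharpness (edges) and pigment mottling (color texture) are the
clinical cues they encode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CHANNEL_ORDER",
    "BINS_PER_CHANNEL",
    "DESCRIPTOR_LENGTH",
    "ColorTextureDescriptor",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "lbp_code_map",
    "lbp_histogram",
    "color_texture_descriptor",
    "sobel_edge_map",
]

CHANNEL_ORDER = ("R", "G", "B", "Y", "U", "V")
BINS_PER_CHANNEL = 59
DESCRIPTOR_LENGTH = len(CHANNEL_ORDER) * BINS_PER_CHANNEL  # 354

# BT.601 full-range RGB -> YUV. U and V are derived exactly from the
# luma row (U = 0.492 (B - Y), V = 0.877 (R - Y)) so equal-RGB inputs
# give *exactly* zero chroma, which rounded textbook constants do not.
_Y_ROW = np.array([0.299, 0.587, 0.114])
_RGB2YUV = np.vstack(
    [
        _Y_ROW,
        0.492 * (np.array([0.0, 0.0, 1.0]) - _Y_ROW),
        0.877 * (np.array([1.0, 0.0, 0.0]) - _Y_ROW),
    ]
)
_YUV2RGB = np.linalg.inv(_RGB2YUV)


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    return image


@dataclass(frozen=True)
class ColorTextureDescriptor:
    """The 354-D descriptor: per-channel L1-normalized uniform-LBP histograms."""

    values: np.ndarray
    channel_order: tuple[str, ...] = CHANNEL_ORDER
    bins_per_channel: int = BINS_PER_CHANNEL

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (DESCRIPTOR_LENGTH,):
            raise ValueError(f"descriptor must have length {DESCRIPTOR_LENGTH}")
        if (v < 0).any():
            raise ValueError("descriptor entries must be non-negative")
        object.__setattr__(self, "values", v)

    def block(self, channel: str) -> np.ndarray:
        i = self.channel_order.index(channel)
        return self.values[i * self.bins_per_channel : (i + 1) * self.bins_per_channel]


def rgb_to_yuv(image: np.ndarray) -> np.ndarray:
    """BT.601 conversion; Y in [0,1], U and V zero-centered."""
    image = _validate_image(image)
    return image @ _RGB2YUV.T


def yuv_to_rgb(yuv: np.ndarray) -> np.ndarray:
    yuv = np.asarray(yuv, dtype=np.float64)
    if yuv.ndim != 3 or yuv.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 array, got shape {yuv.shape}")
    return yuv @ _YUV2RGB.T


# The 8 neighbours at radius 1, clockwise from the top-left, as a fixed
# ring order so circular 0/1 transitions are counted on adjacent bits.
_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def _uniform_code_table() -> np.ndarray:
    """Map each 8-bit ring pattern to its uniform-LBP bin in [0, 58].

    Patterns with at most two circular 0/1 transitions get the 58
    "uniform" bins (indexed by sorted pattern value); everything else
    falls into the catch-all bin 58.
    """
    uniform = []
    for code in range(256):
        bits = [(code >> i) & 1 for i in range(8)]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        if transitions <= 2:
            uniform.append(code)
    table = np.full(256, 58, dtype=np.int64)
    for bin_idx, code in enumerate(sorted(uniform)):
        table[code] = bin_idx
    return table


_UNIFORM_TABLE = _uniform_code_table()
UNIFORM_ALL_ONES_BIN = int(_UNIFORM_TABLE[255])


def lbp_code_map(channel: np.ndarray) -> np.ndarray:
    """Uniform-LBP bin index (0..58) at every pixel of a single channel.

    Neighbours are the 8 adjacent pixels (reflect-padded at the border);
    a neighbour contributes a 1-bit when it is >= the center value.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or channel.size == 0:
        raise ValueError("expected a non-empty 2-D channel")
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite values")
    padded = np.pad(channel, 1, mode="reflect") if min(channel.shape) > 1 else np.pad(
        channel, 1, mode="edge"
    )
    h, w = channel.shape
    codes = np.zeros((h, w), dtype=np.int64)
    for bit, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS):
        neighbor = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        codes |= (neighbor >= channel).astype(np.int64) << bit
    return _UNIFORM_TABLE[codes]


def lbp_histogram(channel: np.ndarray) -> np.ndarray:
    """L1-normalized 59-bin histogram of the channel's LBP codes."""
    codes = lbp_code_map(channel)
    hist = np.bincount(codes.ravel(), minlength=BINS_PER_CHANNEL).astype(np.float64)
    return hist / hist.sum()


def color_texture_descriptor(image: np.ndarray) -> ColorTextureDescriptor:
    """Concatenated per-channel LBP histograms over (R, G, B, Y, U, V)."""
    image = _validate_image(image)
    yuv = rgb_to_yuv(image)
    channels = [image[:, :, i] for i in range(3)] + [yuv[:, :, i] for i in range(3)]
    blocks = [lbp_histogram(ch) for ch in channels]
    return ColorTextureDescriptor(np.concatenate(blocks))


def sobel_edge_map(image: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Sobel gradient magnitude of the BT.601 luma.

    Reflect border handling keeps the output the same size as the input;
    a constant image maps to all zeros. By default the magnitude is
    rescaled to [0, 1] by its maximum (when positive), which keeps the
    reconstruction target commensurate with normalized decoder outputs;
    pass ``normalize=False`` for raw magnitudes, which are the right
    scale for comparing edge strength *between* images.
    """
    image = _validate_image(image)
    luma = rgb_to_yuv(image)[:, :, 0]
    gx = ndimage.sobel(luma, axis=1, mode="reflect")
    gy = ndimage.sobel(luma, axis=0, mode="reflect")
    mag = np.sqrt(gx * gx + gy * gy)
    if normalize:
        peak = mag.max()
        if peak > 0:
            mag = mag / peak
    return mag
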