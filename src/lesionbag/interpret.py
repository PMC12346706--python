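"""Per-patch class evidence and the CTI / EI / overall heatmaps.

Because every backbone cell corresponds to exactly one patch-sized
window and the classifier is affine after global average pooling, the
image logit decomposes into the mean of per-cell logits. For a heatmap,
the image is zero-padded by half a patch on each side and the per-patch
class-k logit l_pk plus the two gate weights A_CTI_p, A_EI_p are
computed for *every* stride-1 window position — one value per pixel.

The raw maps are A_CTI_p * l_pk (color-texture evidence), A_EI_p * l_pk
(edge evidence) and their convex combination weighted by the shares
alpha of positive classifier-weight mass on each half of the feature
vector; each map is min-max normalized independently.

Stride-1 scores are obtained by forwarding all stride^2 crop offsets of
the padded image through the eval-mode (hence strictly local) backbone,
which is bitwise-identical to extracting each window explicitly but
orders of magnitude cheaper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .model import EdgeTextureBagModel

__all__ = [
    "ClassifierWeightView",
    "HeatmapTriple",
    "per_patch_scores",
    "per_patch_scores_explicit",
    "alpha_weights",
    "heatmaps",
    "save_heatmaps",
]


@dataclass(frozen=True)
class ClassifierWeightView:
    """The class-k FC row with negatives zeroed, split into its halves.

    alpha_cti and alpha_ei are the shares of the positive weight mass on
    the CTI and EI halves; they sum to 1 whenever the row has positive
    mass.
    """

    w_fc: np.ndarray
    w_cti_fc: np.ndarray
    w_ei_fc: np.ndarray
    alpha_cti: float
    alpha_ei: float


def alpha_weights(fc_weights: np.ndarray, k: int) -> ClassifierWeightView:
    """Split the class-k classifier row into CTI/EI importance shares.

    ``fc_weights`` is the (2C, n_classes) weight matrix (or a single 2C
    row). Negative entries are zeroed before the sums; an
    all-nonpositive row has undefined shares and falls back to
    (0.5, 0.5) with a warning.
    """
    fc_weights = np.asarray(fc_weights)
    row = fc_weights if fc_weights.ndim == 1 else fc_weights[:, k]
    if row.size % 2:
        raise ValueError("classifier row length must be even (two halves)")
    w = np.maximum(row, 0.0)
    half = row.size // 2
    total = w.sum()
    if total <= 0:
        warnings.warn(
            f"class {k}: classifier row has no positive weight; "
            "falling back to equal alpha shares"
        )
        a_cti = a_ei = 0.5
    else:
        a_cti = float(w[:half].sum() / total)
        a_ei = float(w[half:].sum() / total)
    return ClassifierWeightView(
        w_fc=w, w_cti_fc=w[:half], w_ei_fc=w[half:],
        alpha_cti=a_cti, alpha_ei=a_ei,
    )


def _cell_scores(model: EdgeTextureBagModel, x: Tensor, k: int):
    """Per-cell class-k logits and gate maps for a batch of crops.

    Returns (logit, a_cti, a_ei), each (N, Gh, Gw): the per-cell FC
    response of the concatenated gated features (GAP over a single cell
    is the identity, so this is the per-patch logit).
    """
    feats = model.backbone(x)
    x_cti = model.diverger_cti(feats)
    x_ei = model.diverger_ei(feats)
    x_cti_g, a_cti = model.gate_cti(x_cti)
    x_ei_g, a_ei = model.gate_ei(x_ei)
    w = model.classifier.weight.data[:, k]
    b = float(model.classifier.bias.data[k]) if model.classifier.bias is not None else 0.0
    c = x_cti_g.data.shape[1]
    logit = (
        np.einsum("nchw,c->nhw", x_cti_g.data, w[:c])
        + np.einsum("nchw,c->nhw", x_ei_g.data, w[c:])
        + b
    )
    return logit, a_cti.data[:, 0], a_ei.data[:, 0]


def per_patch_scores(
    model: EdgeTextureBagModel, image: np.ndarray, k: int, batch_size: int = 16
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(l_pk, A_CTI_p, A_EI_p) at every stride-1 window position.

    The image is zero-padded by patch//2 on all sides; each returned map
    has the same height and width as the image (one window per pixel).
    """
    cfg = model.config.backbone
    if k < 0 or k >= model.config.n_classes:
        raise ValueError(f"class {k} out of range [0, {model.config.n_classes})")
    image = np.asarray(image, dtype=np.float64)
    size, patch, stride = cfg.input_size, cfg.patch_size, cfg.stride
    if image.shape != (size, size, 3):
        raise ValueError(f"expected a {size}x{size}x3 image, got {image.shape}")
    pad = patch // 2
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)))
    plen = padded.shape[0]

    logit_map = np.full((size, size), np.nan)
    a_cti_map = np.full((size, size), np.nan)
    a_ei_map = np.full((size, size), np.nan)

    was_training = model.training
    model.eval()
    try:
        with no_grad():
            # group crop offsets by realized crop length so each group
            # forwards as one batch
            groups: dict[int, list[tuple[int, int]]] = {}
            for dy in range(stride):
                for dx in range(stride):
                    ncells_y = (plen - dy - patch) // stride + 1
                    ncells_x = (plen - dx - patch) // stride + 1
                    ly = (ncells_y - 1) * stride + patch
                    lx = (ncells_x - 1) * stride + patch
                    groups.setdefault((ly, lx), []).append((dy, dx))
            for (ly, lx), offsets in groups.items():
                for start in range(0, len(offsets), batch_size):
                    chunk = offsets[start : start + batch_size]
                    crops = np.stack(
                        [padded[dy : dy + ly, dx : dx + lx] for dy, dx in chunk]
                    )
                    xb = Tensor(crops.transpose(0, 3, 1, 2).astype(np.float32))
                    logit, a_cti, a_ei = _cell_scores(model, xb, k)
                    gy, gx = logit.shape[1:]
                    for bi, (dy, dx) in enumerate(chunk):
                        ys = dy + stride * np.arange(gy)
                        xs = dx + stride * np.arange(gx)
                        keep_y = ys < size
                        keep_x = xs < size
                        yy, xx = np.ix_(ys[keep_y], xs[keep_x])
                        logit_map[yy, xx] = logit[bi][np.ix_(keep_y, keep_x)]
                        a_cti_map[yy, xx] = a_cti[bi][np.ix_(keep_y, keep_x)]
                        a_ei_map[yy, xx] = a_ei[bi][np.ix_(keep_y, keep_x)]
    finally:
        model.train(was_training)
    assert not np.isnan(logit_map).any(), "stride-1 coverage incomplete"
    return logit_map, a_cti_map, a_ei_map


def per_patch_scores_explicit(
    model: EdgeTextureBagModel,
    image: np.ndarray,
    k: int,
    positions: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference path: extract each requested window explicitly and
    forward it alone. Used to validate the shift-and-forward identity."""
    cfg = model.config.backbone
    patch = cfg.patch_size
    pad = patch // 2
    padded = np.pad(np.asarray(image, dtype=np.float64), ((pad, pad), (pad, pad), (0, 0)))
    windows = np.stack([padded[y : y + patch, x : x + patch] for y, x in positions])
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            xb = Tensor(windows.transpose(0, 3, 1, 2).astype(np.float32))
            logit, a_cti, a_ei = _cell_scores(model, xb, k)
    finally:
        model.train(was_training)
    return logit[:, 0, 0], a_cti[:, 0, 0], a_ei[:, 0, 0]


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        warnings.warn("constant raw heatmap; normalizing to all zeros")
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


@dataclass
class HeatmapTriple:
    """CTI, EI and overall importance maps in [0, 1] plus raw scores."""

    cti: np.ndarray
    ei: np.ndarray
    overall: np.ndarray
    cti_raw: np.ndarray
    ei_raw: np.ndarray
    overall_raw: np.ndarray
    predicted_class: int
    alpha_cti: float
    alpha_ei: float


def heatmaps(
    model: EdgeTextureBagModel,
    image: np.ndarray,
    k: int | None = None,
    batch_size: int = 16,
) -> HeatmapTriple:
    """The three heatmaps for one image.

    ``k`` defaults to the model's predicted class. Raw maps are
    cti_raw = A_CTI_p * l_pk, ei_raw = A_EI_p * l_pk and overall_raw =
    alpha_CTI * cti_raw + alpha_EI * ei_raw; each is min-max normalized
    independently.
    """
    from .training import predict_proba

    if k is None:
        probs = predict_proba(model, np.asarray(image, dtype=np.float64)[None])
        k = int(probs[0].argmax())
    logit, a_cti, a_ei = per_patch_scores(model, image, k, batch_size=batch_size)
    view = alpha_weights(model.classifier.weight.data, k)
    cti_raw = a_cti * logit
    ei_raw = a_ei * logit
    overall_raw = view.alpha_cti * cti_raw + view.alpha_ei * ei_raw
    return HeatmapTriple(
        cti=_minmax(cti_raw), ei=_minmax(ei_raw), overall=_minmax(overall_raw),
        cti_raw=cti_raw, ei_raw=ei_raw, overall_raw=overall_raw,
        predicted_class=k, alpha_cti=view.alpha_cti, alpha_ei=view.alpha_ei,
    )


def save_heatmaps(triple: HeatmapTriple, out_dir) -> None:
    """Write 8-bit PNGs, raw float arrays (.npy) and a JSON sidecar."""
    from pathlib import Path

    from PIL import Image as PILImage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cti", "ei", "overall"):
        norm = getattr(triple, name)
        raw = getattr(triple, f"{name}_raw")
        PILImage.fromarray((norm * 255).astype(np.uint8)).save(out / f"{name}.png")
        np.save(out / f"{name}_raw.npy", raw)
    (out / "heatmaps.json").write_text(
        json.dumps(
            {
                "predicted_class": triple.predicted_class,
                "alpha_cti": triple.alpha_cti,
                "alpha_ei": triple.alpha_ei,
            },
            indent=2,
        )
    )
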