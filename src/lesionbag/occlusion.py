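"""Heatmap-guided masking and retention analyses.

Candidate windows are all patch-sized windows on the backbone's stride
grid (grid_side^2 of them; they overlap because stride < patch). A
heatmap ranks windows by the sum of its values inside each window, ties
broken in row-major order. Masking zeroes the top-k windows; retention
zeroes everything *outside* them — the two transforms are pixelwise
complementary. The occlusion experiment measures classification
metrics as a function of k for heatmap-guided versus seeded-random
window choices: a faithful heatmap should degrade accuracy much faster
than random masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interpret import heatmaps
from .model import EdgeTextureBagModel
from .training import LabeledImages, metrics_from_scores, predict_proba

__all__ = [
    "PatchRanking",
    "candidate_windows",
    "rank_windows",
    "mask_top_k",
    "retain_top_k",
    "occlusion_experiment",
]


@dataclass(frozen=True)
class PatchRanking:
    """Windows (top-left offsets) sorted by descending heatmap score."""

    windows: tuple[tuple[int, int], ...]
    scores: tuple[float, ...]
    window_size: int

    def __post_init__(self):
        if any(
            self.scores[i] < self.scores[i + 1] for i in range(len(self.scores) - 1)
        ):
            raise ValueError("scores must be non-increasing")
        if len(set(self.windows)) != len(self.windows):
            raise ValueError("duplicate windows in ranking")


def candidate_windows(size: int, window: int, stride: int) -> list[tuple[int, int]]:
    """All stride-grid window offsets, row-major."""
    if (size - window) % stride != 0:
        raise ValueError(
            f"(size - window) = {size - window} not divisible by stride {stride}"
        )
    side = (size - window) // stride + 1
    return [(r * stride, c * stride) for r in range(side) for c in range(side)]


def rank_windows(heatmap: np.ndarray, window: int, stride: int) -> PatchRanking:
    """Rank every candidate window by its heatmap pixel sum (descending;
    row-major tie-break)."""
    heatmap = np.asarray(heatmap, dtype=np.float64)
    if heatmap.ndim != 2 or heatmap.shape[0] != heatmap.shape[1]:
        raise ValueError("heatmap must be square")
    if not np.isfinite(heatmap).all():
        raise ValueError("heatmap contains non-finite values")
    offsets = candidate_windows(heatmap.shape[0], window, stride)
    # integral image makes each window sum O(1)
    ii = np.zeros((heatmap.shape[0] + 1, heatmap.shape[1] + 1))
    ii[1:, 1:] = heatmap.cumsum(axis=0).cumsum(axis=1)
    scores = np.array(
        [
            ii[r + window, c + window] - ii[r, c + window] - ii[r + window, c] + ii[r, c]
            for r, c in offsets
        ]
    )
    order = np.argsort(-scores, kind="stable")  # stable => row-major ties
    return PatchRanking(
        windows=tuple(offsets[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        window_size=window,
    )


def _window_union_mask(
    shape: tuple[int, int], ranking: PatchRanking, k: int
) -> np.ndarray:
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(ranking.windows):
        raise ValueError(f"k={k} exceeds the {len(ranking.windows)} candidate windows")
    mask = np.zeros(shape, dtype=bool)
    w = ranking.window_size
    for r, c in ranking.windows[:k]:
        mask[r : r + w, c : c + w] = True
    return mask


def mask_top_k(image: np.ndarray, ranking: PatchRanking, k: int) -> np.ndarray:
    """Zero the pixels inside the top-k ranked windows."""
    image = np.asarray(image)
    mask = _window_union_mask(image.shape[:2], ranking, k)
    out = image.copy()
    out[mask] = 0.0
    return out


def retain_top_k(image: np.ndarray, ranking: PatchRanking, k: int) -> np.ndarray:
    """Zero the pixels outside the union of the top-k ranked windows."""
    image = np.asarray(image)
    mask = _window_union_mask(image.shape[:2], ranking, k)
    out = image.copy()
    out[~mask] = 0.0
    return out


def _random_ranking(
    size: int, window: int, stride: int, rng: np.random.Generator
) -> PatchRanking:
    offsets = candidate_windows(size, window, stride)
    order = rng.permutation(len(offsets))
    n = len(offsets)
    return PatchRanking(
        windows=tuple(offsets[i] for i in order),
        scores=tuple(float(n - i) for i in range(n)),  # descending placeholder
        window_size=window,
    )


def occlusion_experiment(
    model: EdgeTextureBagModel,
    dataset: LabeledImages,
    k_values: list[int],
    mode: str = "mask",
    ranking_source: str = "model-heatmap",
    seed: int = 0,
    rankings: list[PatchRanking] | None = None,
    batch_size: int = 32,
) -> pd.DataFrame:
    """Metrics as a function of the number of occluded/retained windows.

    ``mode`` is "mask" or "retain"; ``ranking_source`` is
    "model-heatmap" (overall heatmap of each image, computed once),
    "random" (uniform window draws without replacement, seeded), or
    "external" (caller supplies ``rankings``, one per image). k = 0
    reproduces the unmasked baseline exactly.
    """
    if mode not in ("mask", "retain"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = model.config.backbone
    if ranking_source == "model-heatmap":
        rankings = [
            rank_windows(
                heatmaps(model, img).overall_raw, cfg.patch_size, cfg.stride
            )
            for img in dataset.images
        ]
    elif ranking_source == "random":
        rng = np.random.default_rng(seed)
        rankings = [
            _random_ranking(cfg.input_size, cfg.patch_size, cfg.stride, rng)
            for _ in range(len(dataset))
        ]
    elif ranking_source == "external":
        if rankings is None or len(rankings) != len(dataset):
            raise ValueError("external ranking_source requires one ranking per image")
    else:
        raise ValueError(f"unknown ranking_source {ranking_source!r}")

    transform = mask_top_k if mode == "mask" else retain_top_k
    rows = []
    for k in k_values:
        if k == 0 and mode == "mask":
            images = dataset.images
        else:
            images = np.stack(
                [transform(img, r, k) for img, r in zip(dataset.images, rankings)]
            )
        probs = predict_proba(model, images, batch_size=batch_size)
        report = metrics_from_scores(dataset.labels, probs, model.config.n_classes)
        rows.append(
            {
                "k": k,
                "mode": mode,
                "ranking": ranking_source,
                "acc": report.acc,
                "macro_f1": report.macro_f1,
                "macro_auc": report.macro_auc,
            }
        )
    return pd.DataFrame(rows)
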