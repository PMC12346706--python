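"""Losses, sharpness-aware optimization, training loop and metrics.

The total training loss is L = L_S + L_Rec: softmax cross-entropy on
the logits plus a non-rigid reconstruction term

    L_Rec = log(KL(C, z_CTI) + 1) + log(KL(E, E'') + 1)

where each KL term is a sum-reduction KL divergence between the
L1-normalized handcrafted target (descriptor C, edge map E) and the
log-softmax of the corresponding reconstruction, and the log(. + 1)
damps large values.

Optimizers: plain SGD (momentum + weight decay), SAM (gradient
re-evaluated at the adversarially perturbed point w + rho * g / ||g||),
and PSAM, which each step draws an exact random half of all parameter
*elements* and gives that half the SAM gradient while the other half
keeps the plain gradient — a dropout-like source of optimization noise.

Metrics are accuracy, macro F1 and macro one-vs-rest AUC, reported on a
0-100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .autodiff import SGD, Parameter, Tensor, freeze_bn_stats, log_softmax, no_grad
from .features import color_texture_descriptor, sobel_edge_map
from .model import EdgeTextureBagModel

__all__ = [
    "LossBundle",
    "SAMConfig",
    "TrainConfig",
    "MetricsReport",
    "LabeledImages",
    "kl_sum",
    "reconstruction_loss",
    "cross_entropy",
    "total_loss",
    "sam_step",
    "psam_step",
    "cosine_lr",
    "train",
    "predict_proba",
    "evaluate",
]


# -- losses -----------------------------------------------------------


@dataclass
class LossBundle:
    """Total loss and its components. Invariant: L = L_S + L_Rec."""

    loss: Tensor
    l_s: float
    l_rec: float
    kl_cti: float = 0.0
    kl_ei: float = 0.0

    @property
    def total(self) -> float:
        return float(self.loss.data)


def _normalize_target(t: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """L1-normalize each row of a (N, D) target onto the simplex."""
    t = np.asarray(t, dtype=np.float64) + eps
    if (t < 0).any():
        raise ValueError("targets must be non-negative")
    s = t.sum(axis=1, keepdims=True)
    if (s <= 0).any():
        raise ValueError("target rows must have positive mass")
    return t / s


def kl_sum(target: np.ndarray, pred_raw: Tensor) -> Tensor:
    """Sum-reduction KL(target || softmax(pred_raw)) per row.

    ``target`` is (N, D) on the simplex; ``pred_raw`` is a raw (N, D)
    tensor passed through log-softmax. Returns a length-N tensor of
    non-negative divergences.
    """
    target = np.asarray(target, dtype=np.float64)
    if tuple(target.shape) != tuple(pred_raw.shape):
        raise ValueError(
            f"target shape {target.shape} != prediction shape {tuple(pred_raw.shape)}"
        )
    logp = log_softmax(pred_raw, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tlogt = np.where(target > 0, target * np.log(np.where(target > 0, target, 1.0)), 0.0)
    const = tlogt.sum(axis=1)
    cross = (Tensor(target) * logp).sum(axis=1)
    return Tensor(const) - cross


def reconstruction_loss(
    C: np.ndarray,
    z_cti: Tensor,
    E: np.ndarray,
    edge_recon: Tensor,
    eps: float = 1e-8,
) -> tuple[Tensor, dict[str, float]]:
    """L_Rec = log(KL_CTI + 1) + log(KL_EI + 1), averaged over the batch.

    ``C``: (N, 354) descriptors; ``z_cti``: (N, 354) samples; ``E``:
    (N, H, W) edge maps; ``edge_recon``: (N, 1, H, W) reconstructions.
    Single samples may omit the leading batch axis.
    """
    C = np.asarray(C, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    if C.ndim == 1:
        C = C[None]
    if E.ndim == 2:
        E = E[None]
    if z_cti.ndim == 1:
        z_cti = z_cti.reshape(1, -1)
    if edge_recon.ndim == 2:
        edge_recon = edge_recon.reshape(1, 1, *edge_recon.shape)
    n = C.shape[0]
    if E.shape[0] != n or z_cti.shape[0] != n or edge_recon.shape[0] != n:
        raise ValueError("batch sizes of targets and reconstructions must match")
    c_target = _normalize_target(C)
    e_target = _normalize_target(E.reshape(n, -1), eps=eps)
    kl_cti = kl_sum(c_target, z_cti)
    kl_ei = kl_sum(e_target, edge_recon.reshape(n, -1))
    l_rec = ((kl_cti + 1.0).log() + (kl_ei + 1.0).log()).mean()
    parts = {
        "kl_cti": float(kl_cti.data.mean()),
        "kl_ei": float(kl_ei.data.mean()),
    }
    return l_rec, parts


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; targets are integer class indices."""
    targets = np.asarray(targets)
    n, k = logits.shape
    if targets.shape != (n,):
        raise ValueError(f"expected {n} integer targets, got shape {targets.shape}")
    if (targets < 0).any() or (targets >= k).any():
        raise ValueError(f"targets must lie in [0, {k})")
    logp = log_softmax(logits, axis=1)
    return -(logp[np.arange(n), targets].mean())


def total_loss(
    logits: Tensor, targets: np.ndarray, l_rec: Tensor | float = 0.0,
    rec_parts: dict[str, float] | None = None,
) -> LossBundle:
    """L = L_S(logits, targets) + L_Rec."""
    l_s = cross_entropy(logits, targets)
    if isinstance(l_rec, Tensor):
        loss = l_s + l_rec
        l_rec_val = float(l_rec.data)
    else:
        loss = l_s + float(l_rec)
        l_rec_val = float(l_rec)
    parts = rec_parts or {}
    return LossBundle(
        loss=loss, l_s=float(l_s.data), l_rec=l_rec_val,
        kl_cti=parts.get("kl_cti", 0.0), kl_ei=parts.get("kl_ei", 0.0),
    )


# -- sharpness-aware steps --------------------------------------------


@dataclass(frozen=True)
class SAMConfig:
    """Neighborhood radius and the PSAM partition fraction.

    ``psam_fraction`` is the fraction of parameter elements assigned to
    the *general* (plain-gradient) partition; 0.5 is the method default,
    1.0 degenerates to SGD and 0.0 to full SAM.
    """

    rho: float = 0.05
    psam_fraction: float = 0.5

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0.0 <= self.psam_fraction <= 1.0:
            raise ValueError("psam_fraction must lie in [0, 1]")


def _collect_grads(params: list[Parameter]) -> list[np.ndarray]:
    return [np.zeros_like(p.data) if p.grad is None else p.grad.copy() for p in params]


def _grad_norm(grads: list[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g * g).sum()) for g in grads)))


def _perturbed_grads(model, params, closure, base_grads, rho):
    """Gradients evaluated at w + rho * g / ||g|| (w restored afterwards)."""
    norm = _grad_norm(base_grads)
    if rho == 0.0 or norm == 0.0:
        return [g.copy() for g in base_grads]
    saved = [p.data.copy() for p in params]
    scale = rho / norm
    for p, g in zip(params, base_grads):
        p.data = p.data + scale * g
    for p in params:
        p.grad = None
    try:
        with freeze_bn_stats(model):
            closure().loss.backward()
        return _collect_grads(params)
    finally:
        for p, s in zip(params, saved):
            p.data = s


def sam_step(model: EdgeTextureBagModel, closure, opt: SGD, rho: float) -> LossBundle:
    """One sharpness-aware step: ascend by rho along the gradient
    direction, re-evaluate the gradient there, update at the original
    weights with the base optimizer. rho = 0 reduces exactly to SGD;
    a zero gradient skips the perturbation.
    """
    params = opt.params
    opt.zero_grad()
    bundle = closure()
    bundle.loss.backward()
    base_grads = _collect_grads(params)
    new_grads = _perturbed_grads(model, params, closure, base_grads, rho)
    for p, g in zip(params, new_grads):
        p.grad = g
    opt.step()
    return bundle


def psam_step(
    model: EdgeTextureBagModel,
    closure,
    opt: SGD,
    config: SAMConfig,
    rng: np.random.Generator,
) -> LossBundle:
    """One partial-SAM step.

    An exact random half (per ``psam_fraction``) of all parameter
    elements receives the plain gradient and the rest the SAM gradient
    from the same batch; the partition is redrawn from ``rng`` every
    step.
    """
    params = opt.params
    opt.zero_grad()
    bundle = closure()
    bundle.loss.backward()
    base_grads = _collect_grads(params)
    sam_grads = _perturbed_grads(model, params, closure, base_grads, config.rho)

    sizes = [p.data.size for p in params]
    total = int(np.sum(sizes))
    n_general = int(round(config.psam_fraction * total))
    general_mask = np.zeros(total, dtype=bool)
    if 0 < n_general <= total:
        general_mask[rng.permutation(total)[:n_general]] = True
    offset = 0
    for p, gb, gs, size in zip(params, base_grads, sam_grads, sizes):
        m = general_mask[offset : offset + size].reshape(p.data.shape)
        p.grad = np.where(m, gb, gs)
        offset += size
    opt.step()
    return bundle


def cosine_lr(epoch: int, total_epochs: int, lr0: float) -> float:
    """Cosine annealing from lr0 to 0 over the training run."""
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


# -- data & training loop ---------------------------------------------


@dataclass
class LabeledImages:
    """An in-memory labeled image set: (N, H, W, 3) floats in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[3] != 3:
            raise ValueError("images must be (N, H, W, 3)")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images disagree in length")

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters. Defaults are the full-scale recipe:
    SGD momentum 0.9, weight decay 5e-4, batch 16, initial lr 0.002
    with cosine annealing over 100 epochs, PSAM with rho 0.05."""

    epochs: int = 100
    batch_size: int = 16
    lr: float = 0.002
    momentum: float = 0.9
    weight_decay: float = 5e-4
    optimizer: str = "psam"  # "sgd" | "sam" | "psam"
    sam: SAMConfig = dataclass_field(default_factory=SAMConfig)
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in ("sgd", "sam", "psam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    if (h, w) == (size, size):
        return image
    zoom = (size / h, size / w, 1.0)
    return np.clip(ndimage.zoom(image, zoom, order=1), 0.0, 1.0)


def _augment(image: np.ndarray, input_size: int, rng: np.random.Generator) -> np.ndarray:
    """Resize (by the 256:225 factor), random crop, random h/v flip."""
    resized = _resize(image, int(round(input_size * 256 / 225)))
    margin = resized.shape[0] - input_size
    top, left = rng.integers(0, margin + 1, size=2)
    crop = resized[top : top + input_size, left : left + input_size]
    if rng.random() < 0.5:
        crop = crop[:, ::-1]
    if rng.random() < 0.5:
        crop = crop[::-1, :]
    return np.ascontiguousarray(crop)


def center_crop(image: np.ndarray, input_size: int) -> np.ndarray:
    resized = _resize(image, int(round(input_size * 256 / 225)))
    off = (resized.shape[0] - input_size) // 2
    return np.ascontiguousarray(
        resized[off : off + input_size, off : off + input_size]
    )


class _TargetCache:
    """Per-image handcrafted targets, cached when images are static."""

    def __init__(self):
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def get(self, idx: int | None, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if idx is not None and idx in self._cache:
            return self._cache[idx]
        c = color_texture_descriptor(image).values
        e = sobel_edge_map(image)
        if idx is not None:
            self._cache[idx] = (c, e)
        return c, e


def train(
    model: EdgeTextureBagModel,
    train_set: LabeledImages,
    config: TrainConfig,
    val_set: LabeledImages | None = None,
    log=None,
) -> list[dict[str, float]]:
    """Train in place; returns a per-epoch history.

    Each step draws one reparameterization noise pair per batch (reused
    across the SAM ascent/descent passes so both see the same loss
    surface). When a validation set is given, the state with the best
    validation macro F1 is restored at the end.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    input_size = model.config.backbone.input_size
    rng = np.random.default_rng(config.seed)
    opt = SGD(
        model.parameters(), lr=config.lr,
        momentum=config.momentum, weight_decay=config.weight_decay,
    )
    cache = _TargetCache()
    history: list[dict[str, float]] = []
    best_f1, best_state = -1.0, None
    n = len(train_set)
    for epoch in range(config.epochs):
        model.train()
        opt.lr = cosine_lr(epoch, config.epochs, config.lr)
        order = rng.permutation(n)
        epoch_loss, epoch_ls, epoch_lrec, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, cs, es = [], [], []
            for i in idx:
                img = train_set.images[i]
                if config.augment:
                    img = _augment(img, input_size, rng)
                    c, e = cache.get(None, img)
                else:
                    c, e = cache.get(int(i), img)
                xs.append(img)
                cs.append(c)
                es.append(e)
            xb = np.stack(xs).transpose(0, 3, 1, 2).astype(np.float32)
            yb = train_set.labels[idx]
            cb, eb = np.stack(cs), np.stack(es)
            grid = model.config.backbone.grid_size
            eps_cti = rng.standard_normal((len(idx), model.config.cti_dim))
            eps_ei = rng.standard_normal(
                (len(idx), model.config.backbone.channels, grid, grid)
            )

            def closure():
                out = model(Tensor(xb), reconstruct=True,
                            eps_cti=eps_cti, eps_ei=eps_ei)
                l_rec, parts = reconstruction_loss(cb, out.z_cti, eb, out.edge_recon)
                return total_loss(out.logits, yb, l_rec, parts)

            if config.optimizer == "sgd":
                opt.zero_grad()
                bundle = closure()
                bundle.loss.backward()
                opt.step()
            elif config.optimizer == "sam":
                bundle = sam_step(model, closure, opt, config.sam.rho)
            else:
                step_rng = np.random.default_rng(
                    [config.seed, epoch, start // config.batch_size]
                )
                bundle = psam_step(model, closure, opt, config.sam, step_rng)
            epoch_loss += bundle.total
            epoch_ls += bundle.l_s
            epoch_lrec += bundle.l_rec
            n_batches += 1
        entry = {
            "epoch": float(epoch),
            "lr": float(opt.lr),
            "loss": epoch_loss / n_batches,
            "l_s": epoch_ls / n_batches,
            "l_rec": epoch_lrec / n_batches,
        }
        if val_set is not None:
            report = evaluate(model, val_set)
            entry["val_acc"] = report.acc
            entry["val_f1"] = report.macro_f1
            if report.macro_f1 > best_f1:
                best_f1 = report.macro_f1
                best_state = model.state_dict()
        history.append(entry)
        if log is not None:
            log(
                f"epoch {epoch:3d} lr {entry['lr']:.5f} "
                f"L {entry['loss']:.4f} L_S {entry['l_s']:.4f} "
                f"L_Rec {entry['l_rec']:.4f}"
                + (f" val_acc {entry['val_acc']:.2f} val_f1 {entry['val_f1']:.2f}"
                   if val_set is not None else "")
            )
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


# -- evaluation -------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(
    model: EdgeTextureBagModel, images: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Class probabilities for (N, H, W, 3) images (inference path:
    decoders dropped, eval-mode normalization)."""
    images = np.asarray(images)
    input_size = model.config.backbone.input_size
    if images.shape[1] != input_size:
        images = np.stack([center_crop(im, input_size) for im in images])
    was_training = model.training
    model.eval()
    logits = []
    try:
        with no_grad():
            for start in range(0, len(images), batch_size):
                xb = (
                    images[start : start + batch_size]
                    .transpose(0, 3, 1, 2)
                    .astype(np.float32)
                )
                logits.append(model(Tensor(xb)).logits.data)
    finally:
        model.train(was_training)
    return _softmax(np.concatenate(logits, axis=0))


@dataclass
class MetricsReport:
    """Accuracy, macro F1 and macro one-vs-rest AUC on a 0-100 scale."""

    acc: float
    macro_f1: float
    macro_auc: float
    per_class: dict[int, dict[str, float]]
    n: int


def evaluate(
    model: EdgeTextureBagModel, dataset: LabeledImages, batch_size: int = 32
) -> MetricsReport:
    probs = predict_proba(model, dataset.images, batch_size=batch_size)
    return metrics_from_scores(dataset.labels, probs, model.config.n_classes)


def metrics_from_scores(
    labels: np.ndarray, probs: np.ndarray, n_classes: int
) -> MetricsReport:
    """Metrics from per-class scores; classes absent from the truth are
    excluded from the macro AUC with a warning."""
    labels = np.asarray(labels)
    preds = probs.argmax(axis=1)
    acc = accuracy_score(labels, preds) * 100.0
    f1 = f1_score(labels, preds, average="macro", labels=np.arange(n_classes),
                  zero_division=0) * 100.0
    aucs, per_class = [], {}
    for k in range(n_classes):
        mask = labels == k
        cls: dict[str, float] = {
            "support": float(mask.sum()),
            "f1": float(
                f1_score(labels, preds, labels=[k], average="macro", zero_division=0)
                * 100.0
            ),
        }
        if mask.any() and (~mask).any():
            auc = roc_auc_score(mask.astype(int), probs[:, k]) * 100.0
            cls["auc"] = float(auc)
            aucs.append(auc)
        else:
            warnings.warn(
                f"class {k} absent from the ground truth; excluded from macro AUC"
            )
        per_class[k] = cls
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricsReport(
        acc=float(acc), macro_f1=float(f1), macro_auc=macro_auc,
        per_class=per_class, n=len(labels),
    )
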