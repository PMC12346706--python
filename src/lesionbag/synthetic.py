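"""Class-conditional synthetic lesion images with controllable cues.

Each image is a skin-toned textured background carrying one elliptical
lesion. Classes differ along the two clinical cue axes the model is
built to detect:

* edge profile — "abrupt" lesions have a hard pigment cutoff at the
  boundary, "gradual" ones blend over a wide smoothstep ramp (the
  sharp-versus-inconspicuous border distinction dermatologists make);
* texture profile — "uniform" lesions are evenly pigmented, "mottled"
  ones carry multi-scale darker blotches inside the lesion (pigment
  unevenness / color-texture cue).

The default study conditions are three classes — (abrupt, uniform),
(gradual, uniform), (gradual, mottled) — with 100 images per class and
a stratified 60/20/20 train/val/test split, so one class pair differs
only in boundary sharpness and another only in mottling. All
randomness flows through a single seeded generator; the per-image
lesion geometry (and a boundary-band mask) is recorded so heatmap
fidelity can be tested against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .training import LabeledImages

__all__ = [
    "ClassDef",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "generate_fixture",
    "DEFAULT_CLASSES",
]


@dataclass(frozen=True)
class ClassDef:
    edge_profile: str  # "abrupt" | "gradual"
    texture_profile: str  # "uniform" | "mottled"

    def __post_init__(self):
        if self.edge_profile not in ("abrupt", "gradual"):
            raise ValueError(f"unknown edge profile {self.edge_profile!r}")
        if self.texture_profile not in ("uniform", "mottled"):
            raise ValueError(f"unknown texture profile {self.texture_profile!r}")

    @property
    def name(self) -> str:
        return f"{self.edge_profile}-{self.texture_profile}"


DEFAULT_CLASSES = (
    ClassDef("abrupt", "uniform"),
    ClassDef("gradual", "uniform"),
    ClassDef("gradual", "mottled"),
)

# Fixed palette / geometry constants (intensities in [0, 1]):
_SKIN_TONE = np.array([0.82, 0.63, 0.55])
_LESION_TONE = np.array([0.47, 0.30, 0.24])
_BLOTCH_SHIFT = np.array([-0.26, -0.16, -0.06])  # mottling darkens red-shifted
_BACKGROUND_NOISE_AMP = 0.025  # smooth background mottle amplitude
_RAMP_WIDTH = 0.40  # gradual boundary ramp half-width, in radial units
_BLOTCH_THRESHOLD = 0.8  # standardized-field cut: ~20% blob coverage, hard edges
_BAND_HALF_WIDTH_PX = 2.0  # boundary band half-width in pixels


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_per_class: int = 100
    classes: tuple[ClassDef, ...] = DEFAULT_CLASSES
    image_size: int = 225
    noise_sd: float = 0.005
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_occluders: int = 4

    def __post_init__(self):
        if self.max_occluders < 0:
            raise ValueError("max_occluders must be non-negative")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if len({(c.edge_profile, c.texture_profile) for c in self.classes}) < 2:
            raise ValueError("at least two classes must differ in their profiles")
        if self.n_per_class < 1 or self.image_size < 16:
            raise ValueError("invalid n_per_class or image_size")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SyntheticDataset:
    """Generated images plus labels, splits and per-image geometry."""

    images: np.ndarray  # (N, H, W, 3) in [0, 1]
    labels: np.ndarray  # (N,)
    splits: np.ndarray  # (N,) of {"train","val","test"}
    class_names: tuple[str, ...]
    geometry: list[dict]
    boundary_bands: np.ndarray  # (N, H, W) bool
    spec: SyntheticSpec

    def subset(self, split: str) -> LabeledImages:
        mask = self.splits == split
        return LabeledImages(
            images=self.images[mask],
            labels=self.labels[mask],
            class_names=self.class_names,
        )

    def subset_indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.splits == split)


def _smooth_noise(shape, sigma, rng) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _elliptical_radius(size, center, axes, angle) -> np.ndarray:
    """r = 1 on the ellipse boundary, < 1 inside."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return np.sqrt((u / axes[1]) ** 2 + (v / axes[0]) ** 2)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _render_image(
    cls: ClassDef,
    size: int,
    noise_sd: float,
    rng: np.random.Generator,
    max_occluders: int = 2,
) -> tuple[np.ndarray, dict, np.ndarray]:
    # background: skin tone + per-image tint + smooth mottle
    tint = rng.normal(0.0, 0.02, size=3)
    img = np.empty((size, size, 3))
    img[:] = np.clip(_SKIN_TONE + tint, 0, 1)
    bg_noise = _smooth_noise((size, size), sigma=size / 12, rng=rng)
    img += _BACKGROUND_NOISE_AMP * bg_noise[:, :, None]

    # lesion geometry
    center = size / 2 + rng.uniform(-0.08, 0.08, size=2) * size
    axes = rng.uniform(0.22, 0.34, size=2) * size
    angle = rng.uniform(0, np.pi)
    r = _elliptical_radius(size, center, axes, angle)

    if cls.edge_profile == "abrupt":
        alpha = (r <= 1.0).astype(np.float64)
    else:
        alpha = 1.0 - _smoothstep((r - (1.0 - _RAMP_WIDTH)) / (2.0 * _RAMP_WIDTH))

    lesion_color = np.clip(_LESION_TONE + rng.normal(0.0, 0.02, size=3), 0, 1)
    img = img * (1.0 - alpha[:, :, None]) + lesion_color * alpha[:, :, None]

    if cls.texture_profile == "mottled":
        # two blob scales, thresholded to *hard-edged* blobs: the sharp
        # internal boundaries are what makes mottling visible to local
        # ordering statistics (LBP), not just to a global color shift
        fine = _smooth_noise((size, size), sigma=max(size / 40, 1.2), rng=rng)
        coarse = _smooth_noise((size, size), sigma=max(size / 11, 3.0), rng=rng)
        inside = alpha > 0.5
        blobs = (fine > _BLOTCH_THRESHOLD) | (coarse > 2 * _BLOTCH_THRESHOLD)
        img += (blobs & inside)[:, :, None] * _BLOTCH_SHIFT

    img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    # class-independent zero-valued occluder patches: uninformative black
    # regions are part of every image's distribution, so a classifier
    # trained on this world learns to ignore zeroed-out patches (the
    # property occlusion analyses rely on, which large heterogeneous
    # clinical training sets confer naturally)
    occ_size = max(3, int(round(size * 9 / 57)))
    n_occ = int(rng.integers(0, max_occluders + 1)) if max_occluders > 0 else 0
    occluders = []
    for _ in range(n_occ):
        oy, ox = rng.integers(0, size - occ_size + 1, size=2)
        img[oy : oy + occ_size, ox : ox + occ_size] = 0.0
        occluders.append([int(oy), int(ox), int(occ_size)])

    # distance to the boundary in pixels, approximated by the radial
    # deviation scaled by the smaller semi-axis
    band = np.abs(r - 1.0) * min(axes) <= _BAND_HALF_WIDTH_PX
    geometry = {
        "center": [float(c) for c in center],
        "axes": [float(a) for a in axes],
        "angle": float(angle),
        "edge_profile": cls.edge_profile,
        "texture_profile": cls.texture_profile,
        "occluders": occluders,
    }
    return img, geometry, band


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the dataset described by ``spec``; optionally write PNGs,
    ``manifest.csv`` (path,label,split) and ``geometry.json`` to disk."""
    rng = np.random.default_rng(spec.seed)
    images, labels, geoms, bands = [], [], [], []
    for label, cls in enumerate(spec.classes):
        for _ in range(spec.n_per_class):
            img, geo, band = _render_image(
                cls, spec.image_size, spec.noise_sd, rng,
                max_occluders=spec.max_occluders,
            )
            images.append(img)
            labels.append(label)
            geoms.append(geo)
            bands.append(band)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    bands = np.stack(bands)

    # stratified split, seeded
    splits = np.empty(len(labels), dtype=object)
    f_train, f_val, _ = spec.split_fractions
    for label in range(len(spec.classes)):
        idx = np.flatnonzero(labels == label)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(f_train * len(idx)))
        n_val = int(round(f_val * len(idx)))
        splits[idx[:n_train]] = "train"
        splits[idx[n_train : n_train + n_val]] = "val"
        splits[idx[n_train + n_val :]] = "test"
    splits = splits.astype(str)

    dataset = SyntheticDataset(
        images=images, labels=labels, splits=splits,
        class_names=tuple(c.name for c in spec.classes),
        geometry=geoms, boundary_bands=bands, spec=spec,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, starting with a zero run."""
    flat = mask.ravel().astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:
        runs = [0] + runs
    return [int(r) for r in runs]


def _write_dataset(dataset: SyntheticDataset, out_dir: Path) -> None:
    from PIL import Image as PILImage

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "images").mkdir(exist_ok=True)
    rows = ["path,label,split"]
    geo_records = []
    for i, (img, label, split) in enumerate(
        zip(dataset.images, dataset.labels, dataset.splits)
    ):
        rel = f"images/{i:05d}.png"
        PILImage.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / rel)
        rows.append(f"{rel},{dataset.class_names[label]},{split}")
        rec = dict(dataset.geometry[i])
        rec["path"] = rel
        rec["boundary_band_rle"] = _rle_encode(dataset.boundary_bands[i])
        geo_records.append(rec)
    (out_dir / "manifest.csv").write_text("\n".join(rows) + "\n")
    (out_dir / "geometry.json").write_text(json.dumps(geo_records))


def generate_fixture(kind: str = "tiny", n_per_class: int = 100, seed: int = 0) -> SyntheticDataset:
    """Deterministic dataset sized for the tiny (57 px), small (105 px)
    or full (225 px) backbone configuration."""
    if kind == "tiny":
        size = 57
    elif kind == "small":
        size = 105
    elif kind == "full":
        size = 225
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return generate_dataset(
        SyntheticSpec(n_per_class=n_per_class, image_size=size, seed=seed)
    )
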