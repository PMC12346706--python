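"""Manifests, run configuration, checkpoints and image loading.

A dataset manifest is a CSV with columns ``path,label,split`` (split in
{train, val, test}); labels are remapped to contiguous integers in
sorted-name order so the mapping is stable across runs. Checkpoints
are NumPy ``.npz`` archives of the model state dict plus a JSON-encoded
model configuration, which is enough to rebuild and re-evaluate the
model bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbone import BackboneConfig
from .model import EdgeTextureBagModel, ModelConfig
from .training import LabeledImages, SAMConfig, TrainConfig

__all__ = [
    "RunConfig",
    "load_manifest",
    "load_images",
    "load_run_config",
    "save_run_config",
    "save_checkpoint",
    "load_checkpoint",
]

_VALID_SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class RunConfig:
    """Everything one training run needs, serializable to YAML."""

    model: ModelConfig
    train: TrainConfig
    manifest: str | None = None
    out_dir: str = "runs/default"
    seed: int = 0
    repeats: int = 1


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Validated manifest with integer ``label_index`` and checked splits."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = {"path", "label", "split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = df.loc[~df["split"].isin(_VALID_SPLITS)]
    if not bad.empty:
        rows = ", ".join(str(i) for i in bad.index[:5])
        raise ValueError(
            f"unknown split token(s) {sorted(bad['split'].unique())} at row(s) {rows}"
        )
    root = path.parent
    missing_files = [p for p in df["path"] if not (root / p).exists()]
    if missing_files:
        raise FileNotFoundError(
            f"{len(missing_files)} manifest image(s) unreadable, e.g. {missing_files[:3]}"
        )
    names = sorted(df["label"].astype(str).unique())
    mapping = {name: i for i, name in enumerate(names)}
    df = df.copy()
    df["label_index"] = df["label"].astype(str).map(mapping)
    df.attrs["class_names"] = tuple(names)
    df.attrs["root"] = str(root)
    return df


def load_images(manifest: pd.DataFrame, split: str | None = None) -> LabeledImages:
    """Load (and 1/255-scale) the images of one split into memory."""
    from PIL import Image as PILImage

    df = manifest if split is None else manifest[manifest["split"] == split]
    if df.empty:
        raise ValueError(f"no rows for split {split!r}")
    root = Path(manifest.attrs["root"])
    images = np.stack(
        [
            np.asarray(PILImage.open(root / p).convert("RGB"), dtype=np.float64) / 255.0
            for p in df["path"]
        ]
    )
    return LabeledImages(
        images=images,
        labels=df["label_index"].to_numpy(),
        class_names=manifest.attrs["class_names"],
    )


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_config_to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def _model_config_from_dict(d: dict) -> ModelConfig:
    bb = dict(d["backbone"])
    bb["recipe"] = tuple(tuple(layer) for layer in bb.get("recipe", ()))
    return ModelConfig(
        backbone=BackboneConfig(**bb),
        n_classes=d["n_classes"],
        decoder_hidden=d["decoder_hidden"],
        gate_hidden=d["gate_hidden"],
        cti_dim=d["cti_dim"],
    )


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    train_raw = dict(raw.get("train", {}))
    sam = SAMConfig(**train_raw.pop("sam", {}))
    return RunConfig(
        model=_model_config_from_dict(raw["model"]),
        train=TrainConfig(sam=sam, **train_raw),
        manifest=raw.get("manifest"),
        out_dir=raw.get("out_dir", "runs/default"),
        seed=raw.get("seed", 0),
        repeats=raw.get("repeats", 1),
    )


def save_checkpoint(model: EdgeTextureBagModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(_config_to_dict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> EdgeTextureBagModel:
    with np.load(Path(path)) as archive:
        state = {k: archive[k] for k in archive.files}
    config = _model_config_from_dict(
        json.loads(state.pop("__config__").tobytes().decode())
    )
    model = EdgeTextureBagModel(config, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
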