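"""NIfTI case loading, YAML configuration and run logging."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .estimators import HAAUNetSegmenter
from .phantoms import MODALITIES

__all__ = ["load_case", "load_config", "default_config", "RunLogger"]

VALID_LABELS = {0, 1, 2, 3}


def load_case(case_dir) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Load a BraTS-style case directory into a (H, W, 4) stack.

    Modalities are stacked in the fixed order T1, T1Gd, T2, FLAIR by file
    suffix (never listing order).  Returns (image, labels or None, spacing).
    """
    import nibabel as nib

    case_dir = Path(case_dir)
    chans, spacing = [], 1.0
    for mod in MODALITIES:
        matches = sorted(case_dir.glob(f"*_{mod}.nii*"))
        if not matches:
            raise FileNotFoundError(
                f"missing modality '{mod}' in {case_dir}")
        img = nib.load(matches[0])
        spacing = float(abs(img.affine[0, 0]))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        chans.append(data)
    image = np.stack(chans, axis=-1)

    labels = None
    seg = sorted(case_dir.glob("*_seg.nii*"))
    if seg:
        lab = np.asarray(nib.load(seg[0]).dataobj)
        if lab.ndim == 3 and lab.shape[2] == 1:
            lab = lab[:, :, 0]
        labels = lab.astype(np.int64)
        bad = set(np.unique(labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)} in {seg[0]}")
    return image, labels, spacing


def default_config() -> dict:
    est = HAAUNetSegmenter()
    return {"model": {
        "image_size": est.image_size,
        "encoder_channels": list(est.encoder_channels),
        "n_classes": est.n_classes,
        "reduction_ratio": est.reduction_ratio,
        "spatial_kernel": est.spatial_kernel,
        "dropout": est.dropout,
        "use_spatial": est.use_spatial,
        "use_channel": est.use_channel,
        "use_morph": est.use_morph,
    }, "train": {
        "batch_size": est.batch_size,
        "optimizer": "adam",
        "learning_rate": est.learning_rate,
        "lr_decay": est.lr_decay,
        "max_epochs": est.max_epochs,
        "patience": est.patience,
        "seed": est.seed,
    }, "loss": {
        "w1": est.loss_weights[0],
        "w2": est.loss_weights[1],
        "w3": est.loss_weights[2],
        "lambda_attn": est.lambda_attn,
    }}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """YAML config merged over the defaults (shallow per-section merge)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            cfg.setdefault(section, {}).update(vals or {})
    for section, vals in (overrides or {}).items():
        cfg.setdefault(section, {}).update(vals)
    return cfg


def estimator_from_config(cfg: dict) -> HAAUNetSegmenter:
    m, t, l = cfg["model"], cfg["train"], cfg["loss"]
    return HAAUNetSegmenter(
        image_size=m["image_size"],
        encoder_channels=tuple(m["encoder_channels"]),
        n_classes=m["n_classes"], reduction_ratio=m["reduction_ratio"],
        spatial_kernel=m["spatial_kernel"], dropout=m["dropout"],
        use_spatial=m["use_spatial"], use_channel=m["use_channel"],
        use_morph=m["use_morph"],
        loss_weights=(l["w1"], l["w2"], l["w3"]),
        lambda_attn=l["lambda_attn"], batch_size=t["batch_size"],
        learning_rate=t["learning_rate"], lr_decay=t["lr_decay"],
        max_epochs=t["max_epochs"], patience=t["patience"],
        seed=t["seed"])


class RunLogger:
    """JSON-lines run log plus console echo."""

    def __init__(self, path=None, echo: bool = True):
        self.path = Path(path) if path else None
        self.echo = echo
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, **record) -> None:
        line = json.dumps(record, default=float)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
        if self.echo:
            print(line)
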