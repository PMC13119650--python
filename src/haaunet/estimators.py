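"""Training loop and the sklearn-style segmentation estimator.

Training minimizes the composite objective (Dice + cross-entropy + boundary)
plus the attention regularizer with Adam under a per-epoch exponential
learning-rate decay and early stopping on a held-out validation split.  The
boundary term uses a differentiable distance-transform surrogate in the
graph (sum of predicted foreground probability weighted by the normalized
squared distance to the ground-truth class boundary); reported validation
losses use the exact point-set boundary loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._autograd import Adam, Tensor
from .losses import LossConfig, boundary_pixels, total_loss
from .metrics import dice_score
from .network import HAAUNet, ModelConfig, SchamConfig
from .phantoms import composite_views

__all__ = ["TrainConfig", "train_model", "split_indices", "HAAUNetSegmenter"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    batch_size: int = 16
    optimizer: str = "adam"
    initial_lr: float = 1e-4
    lr_decay: float = 0.95
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    val_fraction: float = 0.3
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        self.loss.validate()


def split_indices(n: int, seed: int, fractions=(0.7, 0.15, 0.15)) -> tuple:
    """Deterministic disjoint train/val/test index split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def _boundary_distance_maps(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class normalized squared distance to the GT class boundary.

    Shape (n, H, W, C); the background channel is zero; a class absent from
    a slice gets the maximum penalty 1 everywhere.
    """
    n, h, w = y.shape
    diag = np.sqrt(h ** 2 + w ** 2)
    phi = np.zeros((n, h, w, n_classes), dtype=np.float64)
    for i in range(n):
        for c in range(1, n_classes):
            m = y[i] == c
            if m.any():
                d = ndimage.distance_transform_edt(~boundary_pixels(m))
                phi[i, :, :, c] = (d / diag) ** 2
            else:
                phi[i, :, :, c] = 1.0
    return phi


def _graph_loss(model: HAAUNet, xb, yb, phib, cfg: LossConfig):
    """Composite training loss as an autograd node."""
    n_classes = model.cfg.n_classes
    logp, maps = model.forward(Tensor(xb), training=True,
                               collect_attention=True)
    p = logp.exp()
    onehot = np.eye(n_classes, dtype=model.dtype)[yb]
    phib = np.asarray(phib, dtype=model.dtype)
    npix = float(yb.size)
    eps = 1e-7

    ce = (Tensor(onehot) * logp).sum() * (-1.0 / npix)

    inter = (p * Tensor(onehot)).sum(axis=(0, 1, 2))
    psum = p.sum(axis=(0, 1, 2))
    ysum = Tensor(onehot.sum(axis=(0, 1, 2)))
    dice_c = 1.0 - (inter * 2.0 + eps) / (psum + ysum + eps)
    fg = np.zeros(n_classes, dtype=model.dtype)
    fg[1:] = 1.0 / (n_classes - 1)
    dice = (dice_c * Tensor(fg)).sum()

    bd = (p * Tensor(phib)).sum() * (1.0 / npix)

    loss = dice * cfg.w1 + ce * cfg.w2 + bd * cfg.w3
    if cfg.lambda_attn > 0 and maps:
        reg = None
        for m in maps:
            term = ((m - 0.5) ** 2).sum()
            reg = term if reg is None else reg + term
        loss = loss + reg * cfg.lambda_attn
    return loss


def train_model(model: HAAUNet, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig) -> dict:
    """Fit the network in place; returns the training history.

    Splits (X, y) into train/validation by `val_fraction`, applies per-epoch
    learning rate initial_lr * decay^epoch, and restores the best-validation
    parameters when early stopping triggers.
    """
    cfg.validate()
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model.rng = np.random.default_rng(cfg.seed + 1)  # dropout stream

    n = X.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("dataset too small for the validation fraction")
    phi = _boundary_distance_maps(y, model.cfg.n_classes)

    params = model.parameters()
    opt = Adam(params, lr=cfg.initial_lr)
    history = {"train_loss": [], "val_loss": [], "val_components": [],
               "lr": []}
    best_val, best_state, bad_epochs, n_epochs = np.inf, None, 0, 0

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.initial_lr * cfg.lr_decay ** epoch
        order = rng.permutation(tr_idx)
        batch_losses = []
        for start in range(0, order.size, cfg.batch_size):
            bi = order[start:start + cfg.batch_size]
            loss = _graph_loss(model, X[bi], y[bi], phi[bi], cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        val_total, val_comp = _validation_loss(model, X[val_idx], y[val_idx],
                                               cfg.loss)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_total)
        history["val_components"].append(val_comp)
        history["lr"].append(opt.lr)
        n_epochs = epoch + 1

        if val_total < best_val - 1e-9:
            best_val = val_total
            best_state = [p.data.copy() for p in params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break

    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
    history["n_epochs"] = n_epochs
    history["best_val_loss"] = float(best_val)
    return history


def _validation_loss(model, Xv, yv, loss_cfg) -> tuple[float, dict]:
    """Mean validation loss with the boundary term on the diagonal scale.

    The exact point-set boundary loss is in squared pixels (up to the
    squared image diagonal when a class is still unpredicted), while Dice
    and cross-entropy are O(1); for epoch selection the boundary component
    is normalized by the squared diagonal so all three terms share a scale,
    matching the training surrogate.  The raw components are reported.
    """
    probs = model.predict_proba(Xv)
    diag2 = float(yv.shape[1] ** 2 + yv.shape[2] ** 2)
    totals, comps = [], []
    for i in range(Xv.shape[0]):
        _, c = total_loss(probs[i], yv[i], loss_cfg)
        totals.append(loss_cfg.w1 * c["dice"] + loss_cfg.w2 * c["ce"]
                      + loss_cfg.w3 * c["boundary"] / diag2)
        comps.append(c)
    mean_comp = {k: float(np.mean([c[k] for c in comps])) for k in comps[0]}
    return float(np.mean(totals)), mean_comp


class HAAUNetSegmenter(BaseEstimator):
    """Adaptive-attention U-Net segmenter with an sklearn interface.

    fit(X, y) expects X shaped (n, H, W, 4) (preprocessed modalities) and
    y shaped (n, H, W) with integer labels {0..n_classes-1}.  The three
    ablation flags switch the attention branches of every AAB; with all
    three off (and hence SCHAM bypassed) the network is a plain U-Net.

    Attributes
    ----------
    model_ : the fitted network.
    history_ : per-epoch loss history.
    n_iter_ : epochs actually run.
    """

    def __init__(self, image_size: int = 64,
                 encoder_channels: tuple = (8, 16, 32, 64),
                 n_classes: int = 4, reduction_ratio: int = 16,
                 spatial_kernel: int = 7, dropout: float = 0.2,
                 use_spatial: bool = True, use_channel: bool = True,
                 use_morph: bool = True,
                 loss_weights: tuple = (0.5, 0.3, 0.2),
                 lambda_attn: float = 0.001, batch_size: int = 16,
                 learning_rate: float = 1e-4, lr_decay: float = 0.95,
                 max_epochs: int = 200, patience: int = 30,
                 val_fraction: float = 0.3, seed: int = 0):
        self.image_size = image_size
        self.encoder_channels = encoder_channels
        self.n_classes = n_classes
        self.reduction_ratio = reduction_ratio
        self.spatial_kernel = spatial_kernel
        self.dropout = dropout
        self.use_spatial = use_spatial
        self.use_channel = use_channel
        self.use_morph = use_morph
        self.loss_weights = loss_weights
        self.lambda_attn = lambda_attn
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            input_size=(self.image_size, self.image_size, 4),
            encoder_channels=tuple(self.encoder_channels),
            n_classes=self.n_classes,
            scham=SchamConfig(reduction_ratio=self.reduction_ratio,
                              spatial_kernel=self.spatial_kernel,
                              dropout_p=self.dropout),
            use_spatial=self.use_spatial, use_channel=self.use_channel,
            use_morph=self.use_morph, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        w1, w2, w3 = self.loss_weights
        return TrainConfig(batch_size=self.batch_size,
                           initial_lr=self.learning_rate,
                           lr_decay=self.lr_decay,
                           max_epochs=self.max_epochs,
                           patience=self.patience, seed=self.seed,
                           val_fraction=self.val_fraction,
                           loss=LossConfig(w1, w2, w3, self.lambda_attn))

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.model_ = HAAUNet(self._model_config())
        self.history_ = train_model(self.model_, X, y, self._train_config())
        self.n_iter_ = self.history_["n_epochs"]
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def score(self, X, y):
        """Mean whole-tumor Dice over the given cases."""
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([
            dice_score(composite_views(pred[i])["WT"],
                       composite_views(y[i])["WT"])
            for i in range(y.shape[0])
        ]))
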