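"""Mutual-information feature selection.

Plug-in MI estimate MI(X;Y) = sum_xy P(x,y) log[P(x,y) / (P(x)P(y))] from
empirical joint frequencies (natural log internally, bits on request).
Continuous features are discretized into equal-width (default 16) or
quantile bins; near-constant features (a single occupied bin) get MI = 0
and are dropped first, then the top features by MI against the class labels
are kept (ties broken by original index order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = ["FeatureTable", "mutual_information", "discretize",
           "select_features", "MutualInfoSelector"]

LN2 = np.log(2.0)


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-subject class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list

    def validate(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(m)):
            raise ValueError("feature matrix contains non-finite entries")
        if m.shape[0] != len(self.labels):
            raise ValueError("labels length must match number of subjects")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("labels must have at least 2 classes")
        if m.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str) -> "FeatureTable":
        names = [c for c in df.columns if c != label_col]
        return cls(df[names].to_numpy(dtype=np.float64),
                   df[label_col].to_numpy(), names)


def mutual_information(x, y, units: str = "nats") -> float:
    """Plug-in mutual information between two discrete vectors.

    Zero-probability cells contribute 0 (the 0*log 0 convention).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if x.size == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    mi = max(mi, 0.0)
    return mi / LN2 if units == "bits" else mi


def discretize(values: np.ndarray, bins: int = 16,
               strategy: str = "width") -> np.ndarray:
    """Bin a continuous feature into integer codes.

    'width': equal-width bins over the observed range; 'quantile': equal-mass
    bins (invariant to strictly monotone transforms of the feature).
    """
    v = np.asarray(values, dtype=np.float64)
    if strategy == "width":
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(v.size, dtype=np.int64)
        codes = np.floor((v - lo) / (hi - lo) * bins).astype(np.int64)
        return np.clip(codes, 0, bins - 1)
    if strategy == "quantile":
        edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
        return np.searchsorted(edges, v, side="right").astype(np.int64)
    raise ValueError(f"unknown binning strategy {strategy!r}")


def select_features(table: FeatureTable, keep, bins: int = 16,
                    strategy: str = "width", units: str = "nats"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by MI against the labels and keep the best.

    `keep` is a fraction in (0, 1] or an integer count.  Returns
    (selected indices in rank order, MI score per original feature).
    Near-constant features (single occupied bin) score exactly 0 and can
    never displace an informative feature.
    """
    table.validate()
    x = np.asarray(table.matrix, dtype=np.float64)
    n_feat = x.shape[1]
    if isinstance(keep, (int, np.integer)) and not isinstance(keep, bool):
        n_keep = int(keep)
        if not (1 <= n_keep <= n_feat):
            raise ValueError("keep count out of range")
    else:
        frac = float(keep)
        if not (0 < frac <= 1):
            raise ValueError("keep fraction must be in (0, 1]")
        n_keep = max(1, int(round(frac * n_feat)))

    scores = np.zeros(n_feat)
    for j in range(n_feat):
        codes = discretize(x[:, j], bins=bins, strategy=strategy)
        if np.unique(codes).size < 2:
            scores[j] = 0.0   # isolated / near-constant feature
        else:
            scores[j] = mutual_information(codes, table.labels, units=units)
    order = np.lexsort((np.arange(n_feat), -scores))  # ties: index order
    return order[:n_keep], scores


class MutualInfoSelector(SelectorMixin, BaseEstimator):
    """sklearn-style transformer selecting features by plug-in MI.

    Parameters
    ----------
    keep : float or int, default 0.8
        Fraction (0, 1] or count of features to retain.
    bins : int, default 16
        Number of discretization bins per feature.
    strategy : {'width', 'quantile'}
        Binning scheme.

    Attributes
    ----------
    scores_ : MI of each feature against the labels (nats).
    support_ : boolean mask of the selected features.
    ranking_ : selected feature indices in decreasing-MI order.
    """

    def __init__(self, keep=0.8, bins: int = 16, strategy: str = "width"):
        self.keep = keep
        self.bins = bins
        self.strategy = strategy

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        table = FeatureTable(X, np.asarray(y),
                             [f"f{i}" for i in range(X.shape[1])])
        idx, scores = select_features(table, self.keep, bins=self.bins,
                                      strategy=self.strategy)
        self.n_features_in_ = X.shape[1]
        self.scores_ = scores
        self.ranking_ = idx
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[idx] = True
        return self

    def _get_support_mask(self):
        return self.support_
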