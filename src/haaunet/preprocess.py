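"""Brightness-preserving bi-histogram equalization (BBHE) and normalization.

BBHE splits the 256-bin intensity histogram at the image mean m and equalizes
each sub-histogram within its own output range ([0, m] for the low half,
(m, 255] for the high half), so the global brightness is approximately
preserved while contrast is stretched.  A 3x3 grayscale morphological closing
then removes small dark artifacts, and each modality is z-scored to zero mean
and unit variance before entering the network.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

MAX_LEVEL = 255


def bbhe_equalize(img: np.ndarray) -> np.ndarray:
    """Equalize a [0, 255] intensity slice with the bi-histogram scheme.

    Pixels at or below the image mean m are remapped by their sub-histogram's
    CDF onto [0, m]; pixels above m onto (m, 255].  A constant image (one
    degenerate sub-histogram) is returned unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < 0 or img.max() > MAX_LEVEL:
        raise ValueError("intensities must lie in [0, 255]")
    m = img.mean()
    levels = np.clip(np.round(img), 0, MAX_LEVEL).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=MAX_LEVEL + 1).astype(np.float64)
    m_bin = int(np.floor(m))
    n_low = hist[:m_bin + 1].sum()
    n_high = hist[m_bin + 1:].sum()
    if n_low == 0 or n_high == 0:
        return img.copy()  # degenerate sub-histogram: nothing to equalize

    lut = np.empty(MAX_LEVEL + 1, dtype=np.float64)
    cdf_low = np.cumsum(hist[:m_bin + 1]) / n_low
    lut[:m_bin + 1] = m * cdf_low
    cdf_high = np.cumsum(hist[m_bin + 1:]) / n_high
    lut[m_bin + 1:] = m + (MAX_LEVEL - m) * cdf_high
    # route each pixel through the sub-LUT of its own side of the mean,
    # so the mapping never crosses the boundary m even where rounding
    # would move a pixel across the split bin
    low_side = img <= m
    out = np.empty_like(img)
    out[low_side] = lut[np.minimum(levels[low_side], m_bin)]
    out[~low_side] = lut[np.maximum(levels[~low_side], m_bin + 1)]
    return out


def morph_close(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Grayscale morphological closing (dilation then erosion), flat 3x3 kernel."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("morph_close expects a 2D slice")
    return ndimage.grey_closing(img, size=(size, size), mode="nearest")


def zscore_modalities(slice4: np.ndarray, mask: np.ndarray | None = None,
                      ) -> np.ndarray:
    """Standardize each modality to mean 0, variance 1 (population convention).

    When a brain `mask` is given, the statistics are computed over masked
    pixels only but applied everywhere.
    """
    slice4 = np.asarray(slice4, dtype=np.float64)
    if slice4.ndim != 3:
        raise ValueError("expected an (H, W, C) multi-modal slice")
    out = np.empty_like(slice4)
    for c in range(slice4.shape[2]):
        vals = slice4[:, :, c][mask] if mask is not None else slice4[:, :, c]
        mu, sd = vals.mean(), vals.std()
        if sd == 0:
            raise ValueError(f"modality channel {c} has zero variance")
        out[:, :, c] = (slice4[:, :, c] - mu) / sd
    return out


def _rescale_to_8bit(ch: np.ndarray) -> np.ndarray:
    lo, hi = ch.min(), ch.max()
    if hi == lo:
        return np.zeros_like(ch, dtype=np.float64)
    return (ch - lo) / (hi - lo) * MAX_LEVEL


def preprocess_slice(slice4: np.ndarray, apply_bbhe: bool = True,
                     apply_close: bool = True,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Full pipeline: per-modality BBHE -> 3x3 closing -> z-score.

    Each modality is rescaled to [0, 255] before equalization (BBHE is defined
    on 8-bit intensities); the final z-scoring makes the absolute scale moot.
    """
    slice4 = np.asarray(slice4, dtype=np.float64)
    chans = []
    for c in range(slice4.shape[2]):
        ch = _rescale_to_8bit(slice4[:, :, c])
        if apply_bbhe:
            ch = bbhe_equalize(ch)
        if apply_close:
            ch = morph_close(ch)
        chans.append(ch)
    return zscore_modalities(np.stack(chans, axis=-1), mask=mask)


class BBHEPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer applying the preprocessing pipeline.

    Operates on stacks of multi-modal slices shaped (n, H, W, C).

    Parameters
    ----------
    apply_bbhe : bool
        Disable to ablate the equalization step.
    apply_close : bool
        Disable the 3x3 morphological closing.
    """

    def __init__(self, apply_bbhe: bool = True, apply_close: bool = True):
        self.apply_bbhe = apply_bbhe
        self.apply_close = apply_close

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError("expected (n, H, W, C) stack")
        self.n_features_in_ = X.shape[3]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return np.stack([
            preprocess_slice(X[i], apply_bbhe=self.apply_bbhe,
                             apply_close=self.apply_close)
            for i in range(X.shape[0])
        ])
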