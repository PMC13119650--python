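"""Context-aware morphological features.

Two complementary surfaces:

* :func:`extract_descriptors` computes the six named mask-level shape/texture
  descriptors (solidity, compactness, circularity, GLCM contrast, GLCM
  homogeneity, boundary gradient strength) used as survival covariates.
* :func:`camfm_aggregate` / :func:`morph_branch` realize the in-network
  differentiable morphological stream: per-map standardized operator
  responses combined with adaptive softmax weights from a global-context
  head.  A segmented region does not exist mid-network, so the in-network
  stream uses grayscale morphology residuals; the explicit descriptors are
  reserved for mask-level feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import sobel

from ._autograd import Tensor
from .network import CAMFMBranch

__all__ = ["DescriptorVector", "CamfmWeights", "extract_descriptors",
           "camfm_aggregate", "morph_branch", "DESCRIPTOR_NAMES"]

DESCRIPTOR_NAMES = ("solidity", "compactness", "circularity",
                    "contrast", "texture", "boundary")

GLCM_LEVELS = 8
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class DescriptorVector:
    """The six morphological descriptors of one segmented region.

    solidity = area / convex-hull area, in [0, 1];
    compactness = perimeter^2 / (4 pi area) (1 for a continuum disk);
    circularity = 1 / compactness;
    contrast / texture = GLCM contrast and homogeneity restricted to the
    region (distance 1, four directions, 8 grey levels);
    boundary = mean Sobel gradient magnitude on boundary pixels, normalized
    by the region's intensity range.
    """

    solidity: float
    compactness: float
    circularity: float
    contrast: float
    texture: float
    boundary: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES])


@dataclass
class CamfmWeights:
    """Adaptive aggregation weights; normalized to the simplex."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must not all be zero")
        self.w = w / s

    @property
    def n(self) -> int:
        return self.w.size


def _region_glcm(mask: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """GLCM restricted to the region: pairs touching outside pixels dropped."""
    vals = intensity[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        quant = np.ones_like(intensity, dtype=np.uint8)
    else:
        quant = np.clip(((intensity - lo) / (hi - lo) * GLCM_LEVELS).astype(int),
                        0, GLCM_LEVELS - 1).astype(np.uint8) + 1
    quant = np.where(mask, quant, 0).astype(np.uint8)
    glcm = graycomatrix(quant, distances=[1], angles=list(GLCM_ANGLES),
                        levels=GLCM_LEVELS + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(np.float64)  # drop outside-region level 0
    totals = glcm.sum(axis=(0, 1), keepdims=True)
    totals[totals == 0] = 1.0
    return glcm / totals


def extract_descriptors(mask: np.ndarray, intensity: np.ndarray
                        ) -> DescriptorVector:
    """Compute the six descriptors of a binary region on an intensity slice."""
    mask = np.asarray(mask, dtype=bool)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity must share shape")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mask has no foreground pixels")

    props = measure.regionprops(mask.astype(np.uint8))[0]
    solidity = float(props.solidity)
    perimeter = float(measure.perimeter(mask))
    if perimeter == 0:       # single pixel: use the unit pixel boundary
        perimeter = 4.0
    compactness = perimeter ** 2 / (4.0 * np.pi * area)
    circularity = 1.0 / compactness

    glcm = _region_glcm(mask, intensity)
    contrast = float(graycoprops(glcm, "contrast").mean())
    texture = float(graycoprops(glcm, "homogeneity").mean())

    boundary_px = mask & ~ndimage.binary_erosion(mask)
    grad = sobel(intensity)
    vals = intensity[mask]
    rng_i = max(float(vals.max() - vals.min()), 1e-12)
    boundary = float(grad[boundary_px].mean() / rng_i)

    return DescriptorVector(solidity, compactness, circularity,
                            contrast, texture, boundary)


def _standardize(m: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu, var = m.mean(), m.var()
    return (m - mu) / np.sqrt(var + eps)


def camfm_aggregate(features: list, weights: CamfmWeights) -> np.ndarray:
    """Weighted sum of per-map standardized feature maps (numpy surface).

    Each map is standardized to zero mean / unit variance before the convex
    combination; the caller integrates the result residually with the deep
    features.
    """
    maps = [np.asarray(f, dtype=np.float64) for f in features]
    if len(maps) != weights.n:
        raise ValueError("number of maps must match number of weights")
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"maps disagree in shape: {shapes}")
    out = np.zeros(maps[0].shape)
    for wi, m in zip(weights.w, maps):
        out += wi * _standardize(m)
    return out


def morph_branch(f: np.ndarray, branch: CAMFMBranch | None = None,
                 seed: int = 0, forced_weights: np.ndarray | None = None
                 ) -> np.ndarray:
    """Differentiable morphological stream response of an (h, w, c) map.

    With ``forced_weights`` the context head is bypassed and the given
    simplex weights are applied directly (used to probe single operators).
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected an (h, w, c) feature map")
    branch = branch or CAMFMBranch(f.shape[-1], np.random.default_rng(seed))
    t = Tensor(f[None])
    if forced_weights is None:
        return branch(t).data[0]
    w = CamfmWeights(np.asarray(forced_weights))
    responses = [r.data[0] for r in branch.operator_responses(t)]
    return camfm_aggregate(responses, w)
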