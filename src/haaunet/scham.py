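"""Functional surface of the spatial-channel hybrid attention mechanism.

These wrappers operate on single (h, w, c) numpy feature maps and delegate
to the in-network :class:`~haaunet.network.SCHAM` module, so the functional
and in-network paths share one implementation.  Pass a pre-built module to
control the weights (tests hand-set them); otherwise a seeded module is
constructed on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from .network import SCHAM, SchamConfig

__all__ = ["AttentionMaps", "SchamConfig", "SCHAM", "make_scham",
           "spatial_attention", "channel_attention", "scham_refine"]


@dataclass
class AttentionMaps:
    """Sigmoid attention maps: spatial (h, w, 1) and channel (1, 1, c)."""

    spatial: np.ndarray | None
    channel: np.ndarray | None

    def validate(self) -> None:
        for m in (self.spatial, self.channel):
            if m is not None and (m.min() < 0 or m.max() > 1):
                raise ValueError("attention weights must lie in [0, 1]")


def make_scham(c: int, cfg: SchamConfig | None = None, seed: int = 0) -> SCHAM:
    return SCHAM(c, cfg or SchamConfig(), np.random.default_rng(seed))


def _as_batch(f: np.ndarray) -> Tensor:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected an (h, w, c) feature map")
    return Tensor(f[None])


def spatial_attention(f: np.ndarray, module: SCHAM | None = None,
                      cfg: SchamConfig | None = None, seed: int = 0
                      ) -> np.ndarray:
    """Sigmoid spatial map from channel-wise max/mean pooling + kxk conv."""
    module = module or make_scham(np.asarray(f).shape[-1], cfg, seed)
    return module.spatial_map(_as_batch(f)).data[0]


def channel_attention(f: np.ndarray, module: SCHAM | None = None,
                      cfg: SchamConfig | None = None, seed: int = 0
                      ) -> np.ndarray:
    """Sigmoid channel map from GAP -> squeeze (c/r) -> excite (c)."""
    module = module or make_scham(np.asarray(f).shape[-1], cfg, seed)
    return module.channel_map(_as_batch(f)).data[0]


def scham_refine(f: np.ndarray, cfg: SchamConfig | None = None,
                 training: bool = False, module: SCHAM | None = None,
                 seed: int = 0) -> tuple[np.ndarray, AttentionMaps]:
    """Residual hybrid-attention refinement F + Dropout(F * A_s * A_c).

    In evaluation mode dropout is the identity; the attention maps are
    returned for visualization.
    """
    cfg = cfg or SchamConfig()
    module = module or make_scham(np.asarray(f).shape[-1], cfg, seed)
    rng = np.random.default_rng(seed)
    out, (a_s, a_c) = module.refine(_as_batch(f), training, rng)
    maps = AttentionMaps(
        spatial=None if a_s is None else a_s.data[0],
        channel=None if a_c is None else a_c.data[0],
    )
    maps.validate()
    return out.data[0], maps
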