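"""The hybrid adaptive-attention U-Net (HAAU-Net).

A 4-level encoder--decoder segmentation network in which every level carries
an Adaptive Attention Block (AAB): a learnable convex combination of a
spatial-attention stream, a channel-attention stream and a differentiable
morphological stream,

    AAB(x) = alpha * F_spatial(x) + beta * F_channel(x) + gamma * F_morph(x),

with (alpha, beta, gamma) softmax-normalized per level.  Skip connections
pass encoder features through the spatial-channel hybrid attention module
(SCHAM) before decoder fusion.  Everything runs on the package's own numpy
autograd engine; tensors are NHWC.

Also provides the analytic parameter/MAC profiler used for complexity
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import (Tensor, concat, conv2d, dropout, maxpool2x2,
                        slide_max, slide_min, standardize,
                        upsample_bilinear_2x)

__all__ = ["SchamConfig", "ModelConfig", "AabWeights", "aab_fuse",
           "HAAUNet", "profile_model", "profile_layers", "ComplexityReport",
           "conv_layer_counts", "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchamConfig:
    """Spatial-channel hybrid attention hyperparameters.

    reduction_ratio is the squeeze factor of the channel bottleneck (the
    reduced width is max(1, c // r) so tiny test networks stay valid);
    spatial_kernel is the convolution size over the pooled spatial maps;
    dropout_p applies to the attention-weighted residual branch only.
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    dropout_p: float = 0.2

    def validate(self) -> None:
        if self.spatial_kernel < 3 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd and >= 3")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    input_size: tuple = (224, 224, 4)
    encoder_channels: tuple = (64, 128, 256, 512)
    n_classes: int = 4
    scham: SchamConfig = field(default_factory=SchamConfig)
    use_spatial: bool = True
    use_channel: bool = True
    use_morph: bool = True
    seed: int = 0
    dtype: str = "float32"   # float64 only for numerical-derivative checks

    def validate(self) -> None:
        h, w, c = self.input_size
        if h % 8 != 0 or w % 8 != 0:
            raise ValueError("input height/width must be divisible by 8")
        if len(self.encoder_channels) != 4:
            raise ValueError("encoder depth is fixed at 4 levels")
        if any(ch <= 0 for ch in self.encoder_channels):
            raise ValueError("channel widths must be positive")
        self.scham.validate()

    @property
    def decoder_channels(self) -> tuple:
        return tuple(reversed(self.encoder_channels[:-1]))


@dataclass
class AabWeights:
    """Pre-normalization logits of one AAB's branch weights."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def normalized(self, enabled=(True, True, True)) -> np.ndarray:
        logits = np.array([self.alpha, self.beta, self.gamma], dtype=np.float64)
        mask = np.asarray(enabled, dtype=bool)
        if not mask.any():
            raise ValueError("at least one AAB branch must be enabled")
        e = np.zeros(3)
        z = logits[mask] - logits[mask].max()
        e[mask] = np.exp(z) / np.exp(z).sum()
        return e


def aab_fuse(f_spatial: np.ndarray, f_channel: np.ndarray,
             f_morph: np.ndarray, w: AabWeights,
             enabled=(True, True, True)) -> np.ndarray:
    """Convex combination of the three attention streams (numpy surface)."""
    maps = [np.asarray(f) for f in (f_spatial, f_channel, f_morph)]
    shapes = {m.shape for m, e in zip(maps, enabled) if e}
    if len(shapes) > 1:
        raise ValueError(f"branch maps disagree in shape: {shapes}")
    wn = w.normalized(enabled)
    out = np.zeros(next(iter(shapes)), dtype=np.float64)
    for wi, m, e in zip(wn, maps, enabled):
        if e:
            out = out + wi * m
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Lightweight container with deterministic parameter traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [t for _, t in self.named_parameters()]


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, gain=2.0):
        fan_in = k * k * cin
        std = np.sqrt(gain / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(k, k, cin, cout)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.k, self.cin, self.cout = k, cin, cout

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, cin, cout, rng, gain=2.0):
        std = np.sqrt(gain / cin)
        self.w = Tensor(rng.normal(0.0, std, size=(cin, cout)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class SCHAM(Module):
    """Spatial-channel hybrid attention with residual refinement.

    spatial map:  sigmoid(Conv_kxk(concat(chan-max, chan-mean)))  (h, w, 1)
    channel map:  sigmoid(FC2(relu(FC1(GAP(F)))))                 (1, 1, c)
    refinement:   F + Dropout(F * A_spatial * A_channel)
    """

    def __init__(self, c, cfg: SchamConfig, rng,
                 use_spatial=True, use_channel=True):
        cfg.validate()
        self.cfg = cfg
        self.use_spatial = use_spatial
        self.use_channel = use_channel
        if use_spatial:
            self.conv_sp = Conv2d(2, 1, cfg.spatial_kernel, rng, gain=1.0)
        if use_channel:
            hidden = max(1, c // cfg.reduction_ratio)
            self.fc1 = Dense(c, hidden, rng)
            self.fc2 = Dense(hidden, c, rng, gain=1.0)

    def spatial_map(self, f: Tensor) -> Tensor:
        mx = f.max(axis=-1, keepdims=True)
        av = f.mean(axis=-1, keepdims=True)
        return self.conv_sp(concat([mx, av], axis=-1)).sigmoid()

    def channel_map(self, f: Tensor) -> Tensor:
        n, _, _, c = f.shape
        gap = f.mean(axis=(1, 2))                       # (N, C)
        a = self.fc2(self.fc1(gap).relu()).sigmoid()
        return a.reshape(n, 1, 1, c)

    def refine(self, f: Tensor, training: bool, rng) -> tuple:
        a_s = self.spatial_map(f) if self.use_spatial else None
        a_c = self.channel_map(f) if self.use_channel else None
        attn = f
        if a_s is not None:
            attn = attn * a_s
        if a_c is not None:
            attn = attn * a_c
        if a_s is None and a_c is None:
            return f, (None, None)
        out = f + dropout(attn, self.cfg.dropout_p, rng, training)
        return out, (a_s, a_c)


class CAMFMBranch(Module):
    """Differentiable context-aware morphological feature branch.

    Six grayscale-morphology operator residuals per channel (opening and
    closing residuals at 3x3, morphological gradients at 3x3 and 5x5,
    top-hat and bottom-hat at 5x5), each standardized to zero mean / unit
    variance per sample, aggregated by softmax weights from a global-context
    head (GAP -> dense -> 6 logits).  All operators are built from min/max
    pooling, so the branch is differentiable end to end.
    """

    N_OPERATORS = 6

    def __init__(self, c, rng):
        self.ctx = Dense(c, self.N_OPERATORS, rng, gain=1.0)

    @staticmethod
    def operator_responses(f: Tensor) -> list:
        e3, d3 = slide_min(f, 3), slide_max(f, 3)
        e5, d5 = slide_min(f, 5), slide_max(f, 5)
        open3 = slide_max(e3, 3)
        close3 = slide_min(d3, 3)
        open5 = slide_max(e5, 5)
        close5 = slide_min(d5, 5)
        return [f - open3, close3 - f, d3 - e3, d5 - e5, f - open5, close5 - f]

    @staticmethod
    def standardize(m: Tensor, eps: float = 1e-6) -> Tensor:
        return standardize(m, axes=(1, 2, 3), eps=eps)

    def weights(self, f: Tensor) -> Tensor:
        logits = self.ctx(f.mean(axis=(1, 2)))           # (N, 6)
        return logits.log_softmax(axis=-1).exp()

    def __call__(self, f: Tensor) -> Tensor:
        n = f.shape[0]
        w = self.weights(f)
        out = None
        for i, resp in enumerate(self.operator_responses(f)):
            z = self.standardize(resp)
            term = z * _slice_weight(w, i, n)
            out = term if out is None else out + term
        return out


def _slice_weight(w: Tensor, i: int, n: int) -> Tensor:
    """Select column i of an (N, K) tensor as an (N,1,1,1) broadcastable view."""
    k = w.shape[1]
    onehot = np.zeros((k, 1), dtype=w.data.dtype)
    onehot[i, 0] = 1.0
    return (w @ Tensor(onehot)).reshape(n, 1, 1, 1)


class AAB(Module):
    """Adaptive attention block: softmax-weighted fusion of three streams.

    Shares one SCHAM instance between its spatial/channel streams and the
    skip-connection refinement, so each level computes its attention maps
    once.  Disabled branches are removed from the softmax; with every branch
    disabled the block is an identity passthrough (the plain-U-Net baseline).
    """

    def __init__(self, c, scham_cfg: SchamConfig, rng,
                 use_spatial=True, use_channel=True, use_morph=True):
        self.use_spatial = use_spatial
        self.use_channel = use_channel
        self.use_morph = use_morph
        if use_spatial or use_channel:
            self.scham = SCHAM(c, scham_cfg, rng, use_spatial, use_channel)
        if use_morph:
            self.camfm = CAMFMBranch(c, rng)
        self.logits = {}
        for name, on in (("alpha", use_spatial), ("beta", use_channel),
                         ("gamma", use_morph)):
            if on:
                self.logits[name] = Tensor(np.zeros(()), requires_grad=True)

    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for name, t in self.logits.items():
            yield f"{prefix}logits.{name}", t

    def __call__(self, f: Tensor) -> tuple:
        """Returns (fused map, attention maps list for regularization)."""
        streams, logit_ts, maps = [], [], []
        a_s = a_c = None
        if self.use_spatial:
            a_s = self.scham.spatial_map(f)
            streams.append(f * a_s)
            logit_ts.append(self.logits["alpha"])
            maps.append(a_s)
        if self.use_channel:
            a_c = self.scham.channel_map(f)
            streams.append(f * a_c)
            logit_ts.append(self.logits["beta"])
            maps.append(a_c)
        if self.use_morph:
            streams.append(f + self.camfm(f))
            logit_ts.append(self.logits["gamma"])
        if not streams:
            return f, []
        exps = [t.exp() for t in logit_ts]
        denom = exps[0]
        for e in exps[1:]:
            denom = denom + e
        out = None
        for e, s in zip(exps, streams):
            term = s * (e / denom)
            out = term if out is None else out + term
        return out, maps


class HAAUNet(Module):
    """Full encoder--decoder network with per-level adaptive attention."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.rng = np.random.default_rng(cfg.seed + 1)  # dropout stream
        h, w, cin = cfg.input_size
        chans = cfg.encoder_channels
        flags = dict(use_spatial=cfg.use_spatial, use_channel=cfg.use_channel,
                     use_morph=cfg.use_morph)

        self.enc_convs, self.enc_aabs = [], []
        prev = cin
        for c in chans:
            self.enc_convs.append(Conv2d(prev, c, 3, rng))
            self.enc_aabs.append(AAB(c, cfg.scham, rng, **flags))
            prev = c
        self.bottleneck = Conv2d(chans[-1], chans[-1], 3, rng)

        self.dec_up, self.dec_fuse, self.dec_aabs = [], [], []
        prev = chans[-1]
        for c in cfg.decoder_channels:       # e.g. (256, 128, 64)
            self.dec_up.append(Conv2d(prev, c, 3, rng))
            self.dec_fuse.append(Conv2d(2 * c, c, 3, rng))
            self.dec_aabs.append(AAB(c, cfg.scham, rng, **flags))
            prev = c
        self.head = Conv2d(prev, cfg.n_classes, 1, rng, gain=1.0)
        for _, p in self.named_parameters():
            p.data = p.data.astype(self.dtype)

    # -- forward passes ----------------------------------------------------
    def encoder_forward(self, x: Tensor, collect=None) -> tuple:
        """Algorithm: per level Conv3x3 -> ReLU -> AAB, pooling between levels.

        Returns (bottleneck output, skip features [levels 1..3], pooled maps).
        """
        skips, pooled = [], []
        h = x
        for i in range(4):
            h = self.enc_convs[i](h).relu()
            h, maps = self.enc_aabs[i](h)
            if collect is not None:
                collect.extend(maps)
            if i < 3:
                skips.append(h)
                h = maxpool2x2(h)
                pooled.append(h)
        h = self.bottleneck(h).relu()
        return h, skips, pooled

    def forward(self, x, training: bool = False,
                collect_attention: bool = False):
        """Log-probabilities per pixel, shape (N, H, W, n_classes)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        elif x.data.dtype != self.dtype:
            x = Tensor(x.data.astype(self.dtype), requires_grad=x.requires_grad)
        maps: list = []
        h, skips, _ = self.encoder_forward(x, collect=maps)
        for lvl, skip in enumerate(reversed(skips)):
            h = upsample_bilinear_2x(h)
            h = self.dec_up[lvl](h).relu()
            enc_aab = self.enc_aabs[2 - lvl]
            if enc_aab.use_spatial or enc_aab.use_channel:
                skip_ref, _ = enc_aab.scham.refine(skip, training, self.rng)
            else:
                skip_ref = skip
            h = self.dec_fuse[lvl](concat([h, skip_ref], axis=-1)).relu()
            h, dmaps = self.dec_aabs[lvl](h)
            maps.extend(dmaps)
        logp = self.head(h).log_softmax(axis=-1)
        if collect_attention:
            return logp, maps
        return logp

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.forward(x, training=False).data)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)

    def bottleneck_features(self, x: np.ndarray) -> np.ndarray:
        """Global-average-pooled bottleneck representation (N, C4)."""
        t = Tensor(np.asarray(x, dtype=self.dtype))
        h, _, _ = self.encoder_forward(t)
        return h.data.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: HAAUNet, path) -> None:
    import json
    from dataclasses import asdict

    cfg = asdict(model.cfg)
    arrays = {name: p.data for name, p in model.named_parameters()}
    header = json.dumps({"format_version": CHECKPOINT_VERSION, "config": cfg})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> HAAUNet:
    import json

    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        if header.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        cfg_d = header["config"]
        cfg_d["input_size"] = tuple(cfg_d["input_size"])
        cfg_d["encoder_channels"] = tuple(cfg_d["encoder_channels"])
        cfg_d["scham"] = SchamConfig(**cfg_d["scham"])
        cfg = ModelConfig(**cfg_d)
        model = HAAUNet(cfg)
        for name, p in model.named_parameters():
            p.data = z[name].copy()
    return model


# ---------------------------------------------------------------------------
# analytic complexity profiler
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    parameters: int
    flops: int      # multiply-accumulate count per inference
    per_component: dict


def conv_layer_counts(k: int, cin: int, cout: int, hout: int, wout: int,
                      bias: bool = True) -> tuple:
    """(params, MACs) of one k x k convolution producing an hout x wout map."""
    params = k * k * cin * cout + (cout if bias else 0)
    macs = k * k * cin * cout * hout * wout
    return params, macs


def _dense_counts(cin: int, cout: int) -> tuple:
    return cin * cout + cout, cin * cout


def profile_layers(layers: list) -> ComplexityReport:
    """Aggregate a list of {'component', 'params', 'macs'} layer entries."""
    per: dict = {}
    for lay in layers:
        p, m = per.get(lay["component"], (0, 0))
        per[lay["component"]] = (p + lay["params"], m + lay["macs"])
    total_p = sum(p for p, _ in per.values())
    total_m = sum(m for _, m in per.values())
    return ComplexityReport(total_p, total_m, per)


def model_layers(cfg: ModelConfig) -> list:
    """Enumerate every parameterized layer of a config analytically."""
    cfg.validate()
    h, w, cin = cfg.input_size
    chans = cfg.encoder_channels
    k_sp = cfg.scham.spatial_kernel
    layers = []

    def add(component, params, macs):
        layers.append({"component": component, "params": params, "macs": macs})

    def add_attention(c, hh, ww, component_prefix=""):
        n_branches = 0
        if cfg.use_spatial:
            p, m = conv_layer_counts(k_sp, 2, 1, hh, ww)
            add("spatial_attention", p, m)
            n_branches += 1
        if cfg.use_channel:
            hidden = max(1, c // cfg.scham.reduction_ratio)
            for (ci, co) in ((c, hidden), (hidden, c)):
                p, m = _dense_counts(ci, co)
                add("channel_attention", p, m)
            n_branches += 1
        if cfg.use_morph:
            p, m = _dense_counts(c, CAMFMBranch.N_OPERATORS)
            add("camfm", p, m)
            n_branches += 1
        if n_branches:
            add("aab_weights", n_branches, 0)

    prev, hh, ww = cin, h, w
    for i, c in enumerate(chans):
        p, m = conv_layer_counts(3, prev, c, hh, ww)
        add("encoder", p, m)
        add_attention(c, hh, ww)
        prev = c
        if i < 3:
            hh, ww = hh // 2, ww // 2
    p, m = conv_layer_counts(3, prev, prev, hh, ww)
    add("encoder", p, m)

    for c in cfg.decoder_channels:
        hh, ww = hh * 2, ww * 2
        p, m = conv_layer_counts(3, prev, c, hh, ww)
        add("decoder", p, m)
        p, m = conv_layer_counts(3, 2 * c, c, hh, ww)
        add("decoder", p, m)
        add_attention(c, hh, ww)
        prev = c
    p, m = conv_layer_counts(1, prev, cfg.n_classes, hh, ww)
    add("decoder", p, m)
    return layers


def profile_model(cfg: ModelConfig) -> ComplexityReport:
    """Analytic parameter and MAC counts, broken down by component."""
    return profile_layers(model_layers(cfg))
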