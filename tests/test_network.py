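"""Network architecture, AAB fusion, profiler and checkpoint contracts."""

import numpy as np
import pytest

from haaunet._autograd import Tensor
from haaunet.network import (AabWeights, HAAUNet, ModelConfig, SchamConfig,
                             aab_fuse, conv_layer_counts, load_checkpoint,
                             model_layers, profile_layers, profile_model,
                             save_checkpoint)

TINY = dict(input_size=(16, 16, 4), encoder_channels=(2, 3, 4, 5))


def _tiny_model(**kw) -> HAAUNet:
    return HAAUNet(ModelConfig(**{**TINY, **kw}))


class TestAabFuse:
    def test_softmax_saturation_selects_one_branch(self, rng):
        fs, fc, fm = (rng.normal(size=(4, 4)) for _ in range(3))
        out = aab_fuse(fs, fc, fm, AabWeights(alpha=80.0, beta=0.0, gamma=0.0))
        assert np.allclose(out, fs, atol=1e-20)

    def test_equal_logits_identical_maps(self, rng):
        f = rng.normal(size=(5, 5))
        out = aab_fuse(f, f.copy(), f.copy(), AabWeights())
        assert np.allclose(out, f)

    def test_matches_direct_convex_combination(self, rng):
        maps = [rng.normal(size=(3, 6)) for _ in range(3)]
        w = AabWeights(1.0, 0.0, -1.0)
        e = np.exp([1.0, 0.0, -1.0])
        e /= e.sum()
        expected = sum(wi * m for wi, m in zip(e, maps))
        assert np.allclose(aab_fuse(*maps, w), expected)

    def test_disabled_branches_removed_from_softmax(self, rng):
        fs, fc, fm = (rng.normal(size=(2, 2)) for _ in range(3))
        out = aab_fuse(fs, fc, fm, AabWeights(),
                       enabled=(True, False, True))
        assert np.allclose(out, 0.5 * fs + 0.5 * fm)

    def test_all_disabled_rejected(self, rng):
        f = rng.normal(size=(2, 2))
        with pytest.raises(ValueError, match="enabled"):
            aab_fuse(f, f, f, AabWeights(), enabled=(False,) * 3)


class TestEncoder:
    def test_feature_sides_halve_per_level(self):
        cfg = ModelConfig(input_size=(64, 64, 4),
                          encoder_channels=(8, 16, 32, 64))
        m = HAAUNet(cfg)
        x = Tensor(np.zeros((1, 64, 64, 4), dtype=np.float32))
        bott, skips, pooled = m.encoder_forward(x)
        sides = [s.shape[1] for s in skips] + [bott.shape[1]]
        assert sides == [64, 32, 16, 8]
        chans = [s.shape[3] for s in skips] + [bott.shape[3]]
        assert chans == [8, 16, 32, 64]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_size=(60, 60, 4)).validate()

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(1, 16, 16, 4))
        a = _tiny_model(seed=4).forward(x).data
        b = _tiny_model(seed=4).forward(x).data
        assert np.array_equal(a, b)


class TestForward:
    def test_probability_simplex_per_pixel(self, rng):
        m = _tiny_model()
        p = m.predict_proba(rng.normal(size=(2, 16, 16, 4)) * 10)
        assert p.shape == (2, 16, 16, 4)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_output_shape_contract(self, rng):
        cfg = ModelConfig(input_size=(64, 64, 4),
                          encoder_channels=(4, 8, 12, 16), n_classes=4)
        m = HAAUNet(cfg)
        out = m.predict(rng.normal(size=(1, 64, 64, 4)))
        assert out.shape == (1, 64, 64)

    def test_batch_independence_in_eval(self, rng):
        m = _tiny_model(seed=2)
        x = rng.normal(size=(1, 16, 16, 4))
        batch = np.concatenate([x, x], axis=0)
        p = m.predict_proba(batch)
        assert np.array_equal(p[0], p[1])

    def test_plain_ablation_matches_reference_unet_layer_counts(self):
        cfg = ModelConfig(input_size=(64, 64, 4),
                          encoder_channels=(8, 16, 32, 64),
                          use_spatial=False, use_channel=False,
                          use_morph=False)
        m = HAAUNet(cfg)
        total = sum(p.data.size for p in m.parameters())
        # independent plain-U-Net accounting: encoder convs + bottleneck +
        # decoder (up + fuse per level) + 1x1 head
        def conv_p(k, ci, co):
            return k * k * ci * co + co
        expected = (conv_p(3, 4, 8) + conv_p(3, 8, 16) + conv_p(3, 16, 32)
                    + conv_p(3, 32, 64) + conv_p(3, 64, 64)
                    + conv_p(3, 64, 32) + conv_p(3, 64, 32)
                    + conv_p(3, 32, 16) + conv_p(3, 32, 16)
                    + conv_p(3, 16, 8) + conv_p(3, 16, 8)
                    + conv_p(1, 8, 4))
        assert total == expected
        assert profile_model(cfg).parameters == expected

    def test_aab_logit_gradients_match_finite_differences(self, rng):
        m = HAAUNet(ModelConfig(**TINY, dtype="float64", seed=8))
        x = rng.normal(size=(1, 16, 16, 4))
        y = rng.integers(0, 4, size=(1, 16, 16))
        onehot = np.eye(4)[y]

        def loss():
            logp = m.forward(Tensor(x), training=False)
            return (Tensor(onehot) * logp).sum() * (-1.0 / y.size)

        out = loss()
        out.backward()
        logit = m.enc_aabs[0].logits["alpha"]
        g_an = float(logit.grad)
        eps = 1e-6
        base = float(logit.data)
        logit.data = np.array(base + eps)
        lp = float(loss().data)
        logit.data = np.array(base - eps)
        lm = float(loss().data)
        logit.data = np.array(base)
        g_fd = (lp - lm) / (2 * eps)
        assert g_an == pytest.approx(g_fd, rel=1e-3, abs=1e-9)


class TestProfiler:
    def test_single_conv_oracle(self):
        params, macs = conv_layer_counts(3, 1, 1, 8, 8, bias=False)
        assert (params, macs) == (9, 576)

    def test_doubling_widths_quadruples_conv_params(self):
        cfg1 = ModelConfig(input_size=(64, 64, 4),
                           encoder_channels=(8, 16, 32, 64),
                           use_spatial=False, use_channel=False,
                           use_morph=False)
        cfg2 = ModelConfig(input_size=(64, 64, 4),
                           encoder_channels=(16, 32, 64, 128),
                           use_spatial=False, use_channel=False,
                           use_morph=False)
        r1, r2 = profile_model(cfg1), profile_model(cfg2)
        assert r2.parameters == pytest.approx(4 * r1.parameters, rel=0.1)

    def test_empty_layer_list_is_zero(self):
        rep = profile_layers([])
        assert rep.parameters == 0
        assert rep.flops == 0

    def test_profile_matches_instantiated_parameter_count(self):
        cfg = ModelConfig(**TINY)
        m = HAAUNet(cfg)
        assert profile_model(cfg).parameters == \
            sum(p.data.size for p in m.parameters())

    def test_component_breakdown_covers_all_components(self):
        rep = profile_model(ModelConfig(**TINY))
        assert {"encoder", "decoder", "spatial_attention",
                "channel_attention", "camfm"} <= set(rep.per_component)


class TestCheckpoint:
    def test_round_trip_predictions_bit_exact(self, tmp_path, rng):
        m = _tiny_model(seed=6)
        x = rng.normal(size=(1, 16, 16, 4))
        before = m.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        assert np.array_equal(before, m2.predict_proba(x))

    def test_version_header_checked(self, tmp_path):
        m = _tiny_model()
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        import json
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
        assert header["format_version"] == 1
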