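"""Training loop, data splits, case IO, config and CLI surface."""

import numpy as np
import pytest
import yaml

from haaunet.estimators import (HAAUNetSegmenter, TrainConfig, split_indices,
                                train_model)
from haaunet.io import default_config, estimator_from_config, load_case, load_config
from haaunet.network import HAAUNet, ModelConfig
from haaunet.phantoms import PhantomSpec, generate_phantom, save_case

TINY_TRAIN = dict(image_size=16, encoder_channels=(2, 3, 4, 5),
                  batch_size=4, learning_rate=3e-3, val_fraction=0.25)


def _tiny_data(n=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 16, 16, 4))
    y = np.zeros((n, 16, 16), dtype=int)
    y[:, 4:12, 4:12] = 1
    y[:, 6:10, 6:10] = 2
    return X, y


class TestSplit:
    def test_deterministic_and_disjoint(self):
        a = split_indices(40, seed=3)
        b = split_indices(40, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        all_idx = np.concatenate(a)
        assert sorted(all_idx) == list(range(40))
        assert len(a[0]) == 28 and len(a[1]) == 6 and len(a[2]) == 6


class TestTraining:
    def test_loss_decreases_on_learnable_data(self):
        X, y = _tiny_data(12)
        est = HAAUNetSegmenter(max_epochs=6, seed=1, **TINY_TRAIN)
        est.fit(X, y)
        h = est.history_["train_loss"]
        assert h[-1] < h[0]
        assert est.n_iter_ == 6

    def test_same_seed_reproduces_history(self):
        X, y = _tiny_data(8)
        kw = dict(max_epochs=3, seed=9, **TINY_TRAIN)
        h1 = HAAUNetSegmenter(**kw).fit(X, y).history_
        h2 = HAAUNetSegmenter(**kw).fit(X, y).history_
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_zero_patience_stops_at_first_plateau(self):
        X, y = _tiny_data(8)
        model = HAAUNet(ModelConfig(input_size=(16, 16, 4),
                                    encoder_channels=(2, 2, 2, 2), seed=0))
        cfg = TrainConfig(batch_size=4, initial_lr=0.0, max_epochs=10,
                          patience=0, seed=0, val_fraction=0.25)
        hist = train_model(model, X, y, cfg)
        # lr 0 never improves: first epoch sets the best, second stops
        assert hist["n_epochs"] == 2

    def test_empty_dataset_rejected(self):
        model = HAAUNet(ModelConfig(input_size=(16, 16, 4),
                                    encoder_channels=(2, 2, 2, 2)))
        with pytest.raises(ValueError, match="empty|small"):
            train_model(model, np.empty((0, 16, 16, 4)), np.empty((0, 16, 16)),
                        TrainConfig())

    def test_lr_schedule_is_exponential(self):
        X, y = _tiny_data(8)
        est = HAAUNetSegmenter(max_epochs=3, seed=2, lr_decay=0.5,
                               **{**TINY_TRAIN, "learning_rate": 1e-2})
        est.fit(X, y)
        assert est.history_["lr"] == pytest.approx([1e-2, 5e-3, 2.5e-3])

    def test_train_defaults_follow_reference_recipe(self):
        cfg = TrainConfig()
        assert (cfg.batch_size, cfg.optimizer, cfg.initial_lr,
                cfg.lr_decay, cfg.max_epochs, cfg.patience) == \
            (16, "adam", 1e-4, 0.95, 200, 30)
        assert (cfg.loss.w1, cfg.loss.w2, cfg.loss.w3,
                cfg.loss.lambda_attn) == (0.5, 0.3, 0.2, 0.001)


class TestCaseIO:
    def test_round_trip_bit_exact(self, tmp_path, noisy_phantom):
        img, lab = noisy_phantom
        case = tmp_path / "case_0000"
        save_case(case, img, lab)
        loaded, loaded_lab, spacing = load_case(case)
        assert np.allclose(loaded, img.astype(np.float32), atol=0)
        assert np.array_equal(loaded_lab, lab)
        assert spacing == 1.0

    def test_missing_modality_named(self, tmp_path, noisy_phantom):
        img, lab = noisy_phantom
        case = tmp_path / "case_0001"
        save_case(case, img, lab)
        next(case.glob("*_t2.nii.gz")).unlink()
        with pytest.raises(FileNotFoundError, match="t2"):
            load_case(case)

    def test_stacking_order_fixed_by_suffix(self, tmp_path):
        # channels carry distinct constants; renaming the files must not
        # change which suffix lands in which channel
        img = np.zeros((8, 8, 4))
        for c in range(4):
            img[:, :, c] = 10.0 * (c + 1)
        case = tmp_path / "zz_case"
        save_case(case, img)
        loaded, _, _ = load_case(case)
        for c in range(4):
            assert np.allclose(loaded[:, :, c], 10.0 * (c + 1))

    def test_invalid_label_value_rejected(self, tmp_path, noisy_phantom):
        import nibabel as nib

        img, lab = noisy_phantom
        case = tmp_path / "case_0002"
        bad = lab.copy()
        bad[0, 0] = 5
        save_case(case, img, bad)
        with pytest.raises(ValueError, match="5"):
            load_case(case)


class TestConfig:
    def test_defaults_mirror_reference_table(self):
        cfg = default_config()
        assert cfg["train"]["batch_size"] == 16
        assert cfg["train"]["learning_rate"] == 1e-4
        assert cfg["train"]["lr_decay"] == 0.95
        assert cfg["train"]["patience"] == 30
        assert cfg["loss"] == {"w1": 0.5, "w2": 0.3, "w3": 0.2,
                               "lambda_attn": 0.001}
        assert cfg["model"]["reduction_ratio"] == 16
        assert cfg["model"]["dropout"] == 0.2

    def test_yaml_override(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"train": {"batch_size": 4}}))
        cfg = load_config(path)
        assert cfg["train"]["batch_size"] == 4
        assert cfg["train"]["patience"] == 30
        est = estimator_from_config(cfg)
        assert est.batch_size == 4


class TestCLI:
    def test_phantoms_features_profile_commands(self, tmp_path):
        from click.testing import CliRunner

        from haaunet.cli import main

        runner = CliRunner()
        out_dir = tmp_path / "cases"
        res = runner.invoke(main, ["phantoms", "--n", "1", "--size", "48",
                                   "--seed", "1", "--out", str(out_dir)])
        assert res.exit_code == 0, res.output
        case = next(out_dir.glob("case_*"))
        seg = next(case.glob("*_seg.nii.gz"))
        t1ce = next(case.glob("*_t1ce.nii.gz"))

        feat_csv = tmp_path / "desc.csv"
        res = runner.invoke(main, ["features", "--mask", str(seg),
                                   "--image", str(t1ce),
                                   "--out", str(feat_csv)])
        assert res.exit_code == 0, res.output
        import pandas as pd
        df = pd.read_csv(feat_csv)
        assert set(df["region"]) == {1, 2, 3}
        assert "solidity" in df.columns

        res = runner.invoke(main, ["profile", "--size", "64",
                                   "--channels", "8,16,32,64"])
        assert res.exit_code == 0, res.output
        assert "parameters" in res.output
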