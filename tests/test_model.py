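"""Ensemble construction, the additive (GAM) contract, and joint training."""

import numpy as np
import pytest

from epunet.model import (
    TrainConfig,
    TrainingError,
    build_base_I,
    build_base_II,
    build_epu,
    load_model,
    save_model,
    train,
)
from epunet.nn import Conv2D, Inception


def _random_stacks(rng, n, size=(16, 16), channels=4):
    return rng.uniform(0, 1, size=(n, channels, *size)).astype(np.float32)


def _logit(p):
    return np.log(p / (1 - p))


def _saturate_heads(model, value=1.0):
    """Pin every univariate head to a constant tanh output."""
    for sn in model.subnetworks:
        head = sn.net.layers[-2]
        head.params["W"][:] = 0.0
        head.params["b"][:] = np.arctanh(value) if abs(value) < 1 else 25.0 * np.sign(value)


class TestArchitectures:
    def test_base_i_structure(self):
        sn = build_base_I((128, 128), np.random.default_rng(0))
        assert sn.n_conv_layers == 7
        for _, li in sn.conv_registry:
            conv = sn.net.layers[li - 1]
            assert isinstance(conv, Conv2D) and conv.k == 3
        # three 2x poolings: 128 -> 16 spatial, 256 channels before the head
        dense = next(l for l in sn.net.layers if type(l).__name__ == "Dense")
        assert dense.params["W"].shape[0] == 16 * 16 * 256

    def test_base_i_minimum_input(self):
        sn = build_base_I((8, 8), np.random.default_rng(0))
        out, feats = sn.forward(
            np.random.default_rng(1).normal(size=(1, 1, 8, 8)).astype(np.float32),
            capture_layers=[7],
        )
        assert feats[7].shape == (1, 256, 2, 2)  # 1x1x256 after the final pool
        assert out.shape == (1, 1) and abs(out[0, 0]) <= 1

    def test_base_i_rejects_indivisible_input(self):
        with pytest.raises(ValueError):
            build_base_I((20, 20))

    def test_base_ii_adds_one_leading_inception_block(self):
        rng = np.random.default_rng(0)
        sn2 = build_base_II((32, 32), rng)
        names = [name for name, _ in sn2.conv_registry]
        assert names[0] == "inception"
        assert names[1:] == [f"conv{i}" for i in range(1, 8)]
        inc = sn2.net.layers[0]
        assert isinstance(inc, Inception)
        assert inc.out_ch == sum(inc.widths)

    def test_base_ii_forward_range(self):
        sn = build_base_II((32, 32), np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(2, 1, 32, 32)).astype(np.float32)
        out = sn.forward(x)
        assert out.shape == (2, 1) and np.all(np.abs(out) <= 1)

    def test_base_ii_rejects_indivisible_input(self):
        with pytest.raises(ValueError):
            build_base_II((24, 24))


class TestBuildEpu:
    def test_binary_default_shape(self):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        assert model.n == 4
        assert model.bias.shape == (1,)
        assert model.link == "sigmoid"

    def test_same_seed_identical_parameters(self):
        a = build_epu("base_i", input_size=(16, 16), seed=9)
        b = build_epu("base_i", input_size=(16, 16), seed=9)
        sa, sb = a.state_arrays(), b.state_arrays()
        assert sa.keys() == sb.keys()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_empty_pfm_names_rejected(self):
        with pytest.raises(ValueError):
            build_epu("base_i", pfm_names=(), input_size=(16, 16))

    def test_subnetwork_independence(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=1)
        x = _random_stacks(rng, 2)
        _, rss = model.forward(x)
        x2 = x.copy()
        x2[:, 0] = 0.0
        _, rss2 = model.forward(x2)
        assert not np.allclose(rss[:, 0], rss2[:, 0])
        assert np.array_equal(rss[:, 1:], rss2[:, 1:])


class TestForward:
    def test_zero_scores_give_half(self):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        _saturate_heads(model, 0.0)
        p, rss = model.forward(_random_stacks(np.random.default_rng(0), 3))
        assert np.allclose(rss, 0.0)
        assert np.allclose(p, 0.5)

    def test_all_ones_give_sigmoid_of_four(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        _saturate_heads(model, 1.0)
        p, rss = model.forward(_random_stacks(rng, 2))
        assert np.allclose(rss, 1.0, atol=1e-6)
        assert np.allclose(p, 1 / (1 + np.exp(-4.0)), atol=1e-6)  # ~0.9820

    def test_gam_additivity(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=4)
        model.bias[:] = 0.37
        p, rss = model.forward(_random_stacks(rng, 8))
        err = np.abs(_logit(p) - model.bias[0] - rss.sum(axis=1))
        assert err.max() < 1e-5
        assert np.all(np.abs(rss) <= 1.0)

    def test_prelink_score_within_bias_plus_minus_n(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=4)
        model.bias[:] = -0.5
        scores = model.decision_scores(_random_stacks(rng, 6))
        assert np.all(scores >= model.bias[0] - model.n - 1e-9)
        assert np.all(scores <= model.bias[0] + model.n + 1e-9)

    def test_permutation_equivariance_bit_identical(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=6)
        x = _random_stacks(rng, 4)
        p1, _ = model.forward(x)
        perm = [2, 0, 3, 1]
        model.subnetworks = [model.subnetworks[i] for i in perm]
        model.pfm_names = tuple(model.pfm_names[i] for i in perm)
        p2, _ = model.forward(x[:, perm])
        assert p1.tobytes() == p2.tobytes()

    def test_single_subnetwork_reduces_to_plain_cnn(self, rng):
        model = build_epu("base_i", pfm_names=("only",), input_size=(16, 16), seed=7)
        model.bias[:] = 0.2
        x = _random_stacks(rng, 3, channels=1)
        p, _ = model.forward(x)
        # a directly driven single CNN with the same weights + sigmoid head
        cnn = build_base_I((16, 16), np.random.default_rng(7))
        out = cnn.forward(x[:, 0:1]).astype(np.float64)[:, 0]
        assert np.allclose(p, 1 / (1 + np.exp(-(0.2 + out))), atol=1e-12)

    def test_multiclass_probabilities_sum_to_one(self, rng):
        model = build_epu("base_i", n_classes=3, input_size=(16, 16), seed=2)
        p, rss = model.forward(_random_stacks(rng, 5))
        assert p.shape == (5, 3) and rss.shape == (5, 4, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        with pytest.raises(ValueError):
            model.forward(_random_stacks(rng, 2, channels=3))


class TestTraining:
    def test_one_step_updates_all_subnetworks_and_bias(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=5)
        x = _random_stacks(rng, 4)
        y = np.array([0, 1, 0, 1])
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        train(model, x, y, TrainConfig(epochs=1, batch_size=4, augment=False, seed=0))
        after = model.state_arrays()
        for i in range(model.n):
            changed = any(
                not np.array_equal(before[k], after[k])
                for k in before if k.startswith(f"sn{i}_") and "running" not in k
            )
            assert changed, f"sub-network {i} was not updated"
        assert not np.array_equal(before["bias"], after["bias"])

    def test_initial_loss_near_ln2_on_balanced_data(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=8)
        x = _random_stacks(rng, 16)
        y = np.repeat([0, 1], 8)
        loss, _ = model._loss_and_grad(x, y)
        assert abs(loss - np.log(2)) < 0.15

    def test_single_class_dataset_rejected(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        with pytest.raises(ValueError):
            train(model, _random_stacks(rng, 4), np.zeros(4), TrainConfig(epochs=1))

    def test_divergent_run_raises_training_error(self, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=0)
        x = _random_stacks(rng, 8)
        y = np.tile([0, 1], 4)
        with pytest.raises(TrainingError):
            train(model, x, y,
                  TrainConfig(epochs=3, batch_size=4, lr=1e30, augment=False))

    def test_multiclass_training_step(self, rng):
        model = build_epu("base_i", n_classes=3, input_size=(16, 16), seed=1)
        x = _random_stacks(rng, 6)
        y = np.array([0, 1, 2, 0, 1, 2])
        hist = train(model, x, y,
                     TrainConfig(epochs=1, batch_size=6, augment=False),
                     val_stacks=x, val_y=y)
        assert np.isfinite(hist["loss"][0])
        # initial categorical CE on 3 balanced classes is about ln 3
        assert abs(hist["loss"][0] - np.log(3)) < 0.3
        p, _ = model.forward(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_training_reproducible(self, rng):
        x = _random_stacks(rng, 8)
        y = np.tile([0, 1], 4)
        hists = []
        for _ in range(2):
            m = build_epu("base_i", input_size=(16, 16), seed=3)
            hists.append(
                train(m, x, y, TrainConfig(epochs=2, batch_size=4, seed=11))["loss"]
            )
        assert hists[0] == hists[1]


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_epu("base_i", input_size=(16, 16), seed=1)
        model.bias[:] = 0.63
        x = _random_stacks(rng, 2)
        p1, _ = model.forward(x)
        save_model(model, tmp_path / "ckpt.npz", meta={"note": "roundtrip"})
        loaded = load_model(tmp_path / "ckpt.npz")
        assert loaded.pfm_names == model.pfm_names
        p2, _ = loaded.forward(x)
        assert np.array_equal(p1, p2)
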