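"""Tests of the SelectNet feature-selection network."""

import numpy as np
import pytest

from tonguescreen._nn import Tensor
from tonguescreen.fixtures import make_feature_dataset
from tonguescreen.manual_features import fit_minmax, apply_minmax
from tonguescreen.selectnet import (
    SelectNetConfig, SelectNetModel, _ResBlock1d, res_block_1d,
    scaled_dot_attention, selectnet_forward, train_selectnet,
    feature_importance, select_top_k,
)


def zero_module(module):
    for p in module.parameters():
        p.data[...] = 0.0


def normalized_features(n=120, dim=12, delta=3.0, seed=0):
    fs = make_feature_dataset(n, dim, 3, delta, seed=seed)
    X = np.asarray(apply_minmax(fs.features, fit_minmax(fs.features)), float)
    return X, fs.labels, fs.informative_idx


class TestResBlock:
    def test_zero_weights_is_identity(self, rng):
        block = _ResBlock1d(np.random.default_rng(0))
        zero_module(block)
        x = rng.normal(size=(4, 9))
        assert np.array_equal(res_block_1d(x, block), x)

    def test_shape_preserved(self, rng):
        for f in (3, 8, 17):
            out = res_block_1d(rng.normal(size=(2, f)))
            assert out.shape == (2, f)

    def test_matches_hand_rolled_convolution_oracle(self, rng):
        # direct evaluation of ReLU(Conv(ReLU(Conv(x)))) + x at F=3
        block = _ResBlock1d(np.random.default_rng(3))
        x = rng.normal(size=(1, 3))
        w1 = block.conv1.conv.weight.data[0, 0, 0]  # kernel taps (3,)
        b1 = block.conv1.conv.bias.data[0]
        w2 = block.conv2.conv.weight.data[0, 0, 0]
        b2 = block.conv2.conv.bias.data[0]

        def conv1d(v, w, b):
            padded = np.r_[0.0, v, 0.0]
            return np.array([padded[i:i + 3] @ w for i in range(len(v))]) + b

        expected = np.maximum(conv1d(np.maximum(conv1d(x[0], w1, b1), 0),
                                     w2, b2), 0) + x[0]
        assert np.allclose(res_block_1d(x, block)[0], expected)


class TestChoiceAndAttention:
    def test_fresh_gates_are_uniform(self):
        cfg = SelectNetConfig(feature_dim=6, n_steps=1, seed=0)
        model = SelectNetModel(cfg).eval()
        x = Tensor(np.random.default_rng(1).uniform(size=(4, 6)))
        _, _, s1, _, _ = model.steps[0].choice_block(x, model.steps[0].res(x))
        assert np.allclose(s1.data, 1.0 / 6)

    def test_selection_vector_nonnegative_and_s1_normalised(self, rng):
        cfg = SelectNetConfig(feature_dim=8, n_steps=2, seed=2)
        model = SelectNetModel(cfg).eval()
        # random parameters: the softmax contracts must hold regardless
        for p in model.parameters():
            p.data[...] = rng.normal(size=p.data.shape)
        _, record = selectnet_forward(rng.uniform(size=(5, 8)), model)
        for s1, m in zip(record.S1, record.M):
            assert np.allclose(s1.sum(axis=1), 1.0)
            assert (m >= 0).all()

    def test_zero_input_gives_zero_weighted(self):
        cfg = SelectNetConfig(feature_dim=5, n_steps=1, seed=3)
        model = SelectNetModel(cfg).eval()
        x = Tensor(np.zeros((3, 5)))
        weighted, *_ = model.steps[0].choice_block(x, model.steps[0].res(x))
        assert np.array_equal(weighted.data, np.zeros((3, 5)))

    def test_attention_rows_sum_to_one(self, rng):
        q = Tensor(rng.normal(size=(2, 3, 4)))
        k = Tensor(rng.normal(size=(2, 5, 4)))
        v = Tensor(rng.normal(size=(2, 5, 6)))
        _, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.data.sum(axis=-1), 1.0)

    def test_single_key_gets_weight_one(self, rng):
        q = Tensor(rng.normal(size=(1, 1, 4)))
        k = Tensor(rng.normal(size=(1, 1, 4)))
        v = Tensor(rng.normal(size=(1, 1, 2)))
        out, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.data, 1.0)
        assert np.allclose(out.data, v.data)

    def test_zero_value_projection_reduces_to_batchnorm(self, rng):
        cfg = SelectNetConfig(feature_dim=4, n_steps=1, seed=4)
        model = SelectNetModel(cfg)
        step = model.steps[0]
        zero_module(step.wv)
        x = Tensor(rng.normal(size=(6, 4)))
        trans = Tensor(np.zeros((6, 4)))
        x_step = Tensor(rng.normal(size=(6, 4)))
        x_dec, _ = step.attention_block(x, trans, x_step)
        assert np.allclose(x_dec.data, step.bn_decision(x).data)


class TestForwardAndTraining:
    def test_probs_normalised_and_deterministic(self, rng):
        cfg = SelectNetConfig(feature_dim=10, seed=5)
        model = SelectNetModel(cfg)
        x = rng.uniform(size=(7, 10))
        p1, rec = selectnet_forward(x, model)
        p2, _ = selectnet_forward(x, model)
        assert np.allclose(p1.sum(axis=1), 1.0) and (p1 >= 0).all()
        assert np.array_equal(p1, p2)
        assert rec.importance.sum() == pytest.approx(1.0)
        assert (rec.importance >= 0).all()

    def test_fully_zeroed_network_is_uninformative_identity_chain(self):
        cfg = SelectNetConfig(feature_dim=6, n_steps=2, seed=6)
        model = SelectNetModel(cfg).eval()
        zero_module(model)
        x = np.random.default_rng(0).uniform(size=(5, 6))
        probs, rec = selectnet_forward(x, model)
        assert np.allclose(probs, 0.5)  # zeroed head is uninformative
        for s1 in rec.S1:
            assert np.allclose(s1, 1.0 / 6)  # stage-1 gates exactly uniform
        assert rec.importance.sum() == pytest.approx(1.0)

    def test_nan_input_rejected(self):
        model = SelectNetModel(SelectNetConfig(feature_dim=3, seed=0))
        with pytest.raises(ValueError):
            selectnet_forward(np.array([[np.nan, 0, 0]]), model)

    def test_loss_decreases_on_separable_data(self):
        X, y, _ = normalized_features()
        cfg = SelectNetConfig(feature_dim=X.shape[1], epochs=12, seed=7)
        model = train_selectnet(X, y, cfg)
        assert model.training_log[-1] < model.training_log[0]

    def test_training_bit_reproducible(self):
        X, y, _ = normalized_features(n=60, dim=8)
        cfg = SelectNetConfig(feature_dim=8, epochs=3, seed=8)
        a = train_selectnet(X, y, cfg)
        b = train_selectnet(X, y, cfg)
        for pa, pb in zip(a.state_arrays(), b.state_arrays()):
            assert np.array_equal(pa, pb)

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).uniform(size=(20, 4))
        with pytest.raises(ValueError):
            train_selectnet(X, np.zeros(20, int),
                            SelectNetConfig(feature_dim=4, epochs=1, seed=0))

    def test_save_load_round_trip(self, tmp_path):
        X, y, _ = normalized_features(n=60, dim=8)
        cfg = SelectNetConfig(feature_dim=8, epochs=2, seed=9)
        model = train_selectnet(X, y, cfg)
        model.save(tmp_path / "m.npz")
        loaded = SelectNetModel.load(tmp_path / "m.npz")
        pa, _ = selectnet_forward(X, model)
        pb, _ = selectnet_forward(X, loaded)
        assert np.array_equal(pa, pb)


@pytest.fixture(scope="module")
def trained():
    X, y, _ = normalized_features(n=200, dim=12)
    cfg = SelectNetConfig(feature_dim=12, epochs=20, seed=10)
    return train_selectnet(X, y, cfg), X


class TestTopK:
    def test_k_equals_f_keeps_everything(self, trained):
        model, X = trained
        reduced, idx = select_top_k(model, X, 12)
        assert np.array_equal(np.sort(idx), np.arange(12))
        assert np.array_equal(reduced, X)

    def test_k_one_is_argmax(self, trained):
        model, X = trained
        imp = feature_importance(model, X)
        _, idx = select_top_k(model, X, 1)
        assert idx[0] == np.argmax(imp)

    def test_subset_preserves_column_order(self, trained):
        model, X = trained
        reduced, idx = select_top_k(model, X, 5)
        assert np.array_equal(idx, np.sort(idx))
        assert np.array_equal(reduced, X[:, idx])

    def test_k_too_large_raises(self, trained):
        model, X = trained
        with pytest.raises(ValueError):
            select_top_k(model, X, 13)
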