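"""Tests of the shuttle-attention block and the residual CNN branch."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tonguescreen._nn import Tensor, Module
from tonguescreen.fixtures import SyntheticImageParams, make_image_dataset
from tonguescreen.shuttle_attention import (
    ShuttleConfig, group_split, channel_shuffle, ChannelAttention,
    SpatialAttention, ShuttleBlock, ShuttleResNet, build_model,
    train_cnn_branch, predict_proba,
)


class _Identity(Module):
    def __call__(self, x):
        return x


def shuffle_index_oracle(c, g):
    """Brute-force index map of the reshape-transpose channel shuffle."""
    return [(i % g) * (c // g) + i // g for i in range(c)]


class TestGroupSplit:
    def test_sizes(self, rng):
        x = rng.normal(size=(2, 8, 4, 4))
        groups = group_split(x, 2)
        assert len(groups) == 2
        for x1, x2 in groups:
            assert x1.shape[1] == 2 and x2.shape[1] == 2

    def test_round_trip_identity(self, rng):
        x = rng.normal(size=(1, 12, 3, 3))
        parts = [h for pair in group_split(x, 3) for h in pair]
        assert np.array_equal(np.concatenate(parts, axis=1), x)

    def test_divisibility_error(self, rng):
        with pytest.raises(ValueError):
            group_split(rng.normal(size=(1, 6, 2, 2)), 4)


class TestChannelShuffle:
    def test_c4_g2_permutation(self):
        x = np.arange(4).reshape(1, 4, 1, 1).astype(float)
        out = channel_shuffle(x, 2)
        assert out[0, :, 0, 0].tolist() == [0, 2, 1, 3]

    def test_g1_identity(self, rng):
        x = rng.normal(size=(2, 6, 3, 3))
        assert np.array_equal(channel_shuffle(x, 1), x)

    def test_matches_index_oracle_for_all_divisors(self):
        for c in range(2, 25):
            for g in range(1, c + 1):
                if c % g:
                    continue
                x = np.arange(c).reshape(1, c, 1, 1).astype(float)
                out = channel_shuffle(x, g)[0, :, 0, 0].astype(int).tolist()
                assert out == shuffle_index_oracle(c, g), (c, g)

    def test_shuffle_composition_inverts(self):
        c, g = 12, 3
        x = np.arange(c).reshape(1, c, 1, 1).astype(float)
        back = channel_shuffle(channel_shuffle(x, g), c // g)
        assert np.array_equal(back, x)

    def test_divisibility_error(self):
        with pytest.raises(ValueError):
            channel_shuffle(np.zeros((1, 5, 2, 2)), 2)

    def test_tensor_and_array_paths_agree(self, rng):
        x = rng.normal(size=(2, 8, 3, 3))
        assert np.array_equal(channel_shuffle(Tensor(x), 4).data,
                              channel_shuffle(x, 4))


class TestAttentionBranches:
    def test_zero_linear_scales_by_half(self, rng):
        ca = ChannelAttention(3, np.random.default_rng(0))
        ca.linear.weight.data[...] = 0.0
        ca.linear.bias.data[...] = 0.0
        x = rng.normal(size=(2, 3, 4, 4))
        out = ca(Tensor(x)).data
        assert np.allclose(out, 0.5 * x)  # sigmoid(0) = 0.5

    def test_constant_map_identity_linear_closed_form(self):
        c = 1.7
        ca = ChannelAttention(2, np.random.default_rng(0))
        ca.linear.weight.data[...] = np.eye(2)
        ca.linear.bias.data[...] = 0.0
        x = np.full((1, 2, 3, 3), c)
        out = ca(Tensor(x)).data
        sig = 1 / (1 + np.exp(-c))  # GAP of a constant map is the constant
        assert np.allclose(out, sig * c)

    def test_spatially_constant_input_uniform_weights(self, rng):
        sa = SpatialAttention(4, np.random.default_rng(1))
        x = np.full((2, 4, 5, 5), 3.3)
        out = sa(Tensor(x)).data
        # group-norm of a constant field is 0; weight = sigmoid(conv bias)
        bias = sa.conv.bias.data[0]
        assert np.allclose(out, x / (1 + np.exp(-bias)))

    @given(st.integers(0, 2**31 - 1))
    def test_weights_strictly_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        ca = ChannelAttention(3, r)
        sa = SpatialAttention(3, r)
        x = Tensor(r.normal(0, 10, size=(2, 3, 4, 4)))
        gap = x.mean(axis=(2, 3))
        wc = ca.linear(gap).sigmoid().data
        ws = sa.conv(sa.norm(x)).sigmoid().data
        assert (0 < wc).all() and (wc < 1).all()
        assert (0 < ws).all() and (ws < 1).all()

    def test_shapes_preserved(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 6, 6)))
        assert ChannelAttention(4, rng)(x).shape == x.shape
        assert SpatialAttention(4, rng)(x).shape == x.shape


class TestShuttleBlock:
    def test_shape_preserved(self, rng):
        blk = ShuttleBlock(16, 4, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 16, 5, 5)))
        assert blk(x).shape == x.shape

    @pytest.mark.parametrize("c,g", [(4, 1), (8, 2), (8, 4), (12, 3), (16, 4)])
    def test_unit_weights_reduce_to_pure_channel_shuffle(self, c, g, rng):
        blk = ShuttleBlock(c, g, np.random.default_rng(0))
        blk.channel_attn = _Identity()
        blk.second_attn = _Identity()
        x = rng.normal(size=(2, c, 3, 3))
        out = blk(Tensor(x)).data
        assert np.array_equal(out, channel_shuffle(x, g))

    def test_gradient_reaches_every_input_channel(self, rng):
        blk = ShuttleBlock(8, 2, np.random.default_rng(2))
        x = Tensor(rng.normal(size=(1, 8, 4, 4)), requires_grad=True)
        blk(x).sum().backward()
        per_channel = np.abs(x.grad).sum(axis=(0, 2, 3))
        assert (per_channel > 0).all()

    def test_double_channel_attention_variant(self, rng):
        blk = ShuttleBlock(8, 2, np.random.default_rng(3),
                           double_channel_attention=True)
        assert isinstance(blk.second_attn, ChannelAttention)
        x = Tensor(rng.normal(size=(1, 8, 3, 3)))
        assert blk(x).shape == x.shape


class TestModel:
    def test_mini_forward_probabilities(self, rng):
        model = build_model(ShuttleConfig(seed=0)).eval()
        x = Tensor(rng.normal(size=(2, 3, 64, 64)))
        p = model(x).data
        assert p.shape == (2, 2)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_param_count_difference_is_attention_layers(self):
        cfg = ShuttleConfig(seed=0)
        with_shuttle = build_model(cfg, use_shuttle=True)
        without = build_model(cfg, use_shuttle=False)
        attn_params = sum(
            p.data.size
            for blk in with_shuttle.blocks
            for p in blk.shuttle.parameters()
        )
        assert with_shuttle.n_parameters() - without.n_parameters() == attn_params

    def test_seeded_init_reproducible(self):
        a = build_model(ShuttleConfig(seed=5))
        b = build_model(ShuttleConfig(seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_resnet50_backbone_constructs(self):
        model = build_model(ShuttleConfig.resnet50_profile(seed=0))
        assert model.n_parameters() > 20_000_000

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_model(ShuttleConfig(backbone="vgg", seed=0))


@pytest.fixture(scope="module")
def tiny_images():
    params = SyntheticImageParams(height=32, width=32, color_effect=40.0,
                                  seed=20)
    return make_image_dataset(16, params)


class TestTraining:
    def test_deterministic_scores_and_loss_decreases(self, tiny_images):
        ds = tiny_images
        cfg = ShuttleConfig(seed=1, epochs=2, input_size=32, batch_size=8)
        _, s1 = train_cnn_branch(ds.images, ds.masks, ds.labels, cfg)
        model, s2 = train_cnn_branch(ds.images, ds.masks, ds.labels, cfg)
        assert np.array_equal(s1, s2)
        assert model.training_log[-1] < model.training_log[0]
        assert ((s2 >= 0) & (s2 <= 1)).all()

    def test_save_load_round_trip(self, tiny_images, tmp_path):
        ds = tiny_images
        cfg = ShuttleConfig(seed=2, epochs=1, input_size=32, batch_size=8)
        model, _ = train_cnn_branch(ds.images, ds.masks, ds.labels, cfg)
        model.save(tmp_path / "cnn.npz")
        loaded = ShuttleResNet.load(tmp_path / "cnn.npz")
        pa = predict_proba(model, ds.images, ds.masks)
        pb = predict_proba(loaded, ds.images, ds.masks)
        assert np.array_equal(pa, pb)

    def test_single_class_rejected(self, tiny_images):
        ds = tiny_images
        with pytest.raises(ValueError):
            train_cnn_branch(ds.images, ds.masks, np.zeros(len(ds), int),
                             ShuttleConfig(seed=0, epochs=1, input_size=32))
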