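"""Backbone construction, head replacement, pruning, freezing, serialization."""

import numpy as np
import pytest

from ultracat import _nn
from ultracat.errors import WeightMismatchError
from ultracat.models import (
    BackboneConfig,
    DEFAULT_CONFIG,
    load_checkpoint,
    make_backbone,
    parameter_checksum,
    prune_conv_layers,
    replace_head,
    save_checkpoint,
    set_trainable,
    small_preset,
)


@pytest.fixture(scope="module")
def small_model():
    return make_backbone(small_preset(K=3), seed=0)


class TestArchitecture:
    def test_default_is_13_convs_in_5_blocks(self):
        assert DEFAULT_CONFIG.depth == 13
        assert len(DEFAULT_CONFIG.convs_per_block) == 5
        assert DEFAULT_CONFIG.channels == (64, 128, 256, 512, 512)
        m = make_backbone(DEFAULT_CONFIG, seed=0)
        assert m.depth == 13
        assert m.n_blocks == 5

    def test_adaptive_pooling_side_constant_across_resolutions(self):
        m = make_backbone(DEFAULT_CONFIG, seed=0)
        for side in (32, 64):
            img = np.zeros((side, side, 3), dtype=np.uint8)
            feats = m.pooled_features(img)
            assert feats.shape == (1, 512, 7, 7)

    def test_forward_output_dimension_is_K(self, small_model):
        img = np.zeros((2, 64, 64, 3), dtype=np.uint8)
        assert small_model.scores(img).shape == (2, 3)

    def test_seeded_construction_is_deterministic(self):
        a = make_backbone(small_preset(K=3), seed=5)
        b = make_backbone(small_preset(K=3), seed=5)
        assert parameter_checksum(a) == parameter_checksum(b)
        c = make_backbone(small_preset(K=3), seed=6)
        assert parameter_checksum(a) != parameter_checksum(c)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BackboneConfig(channels=(8, 16), convs_per_block=(1, 1, 1))
        with pytest.raises(ValueError):
            BackboneConfig(K=0)


class TestWeightInjection:
    def test_matching_weights_are_loaded(self, small_model):
        weights = {k: v + 1.0 for k, v in small_model.state_dict().items()}
        m = make_backbone(small_preset(K=3), seed=1, weights=weights)
        assert np.array_equal(m.state_dict()["conv0.W"], weights["conv0.W"])

    def test_shape_mismatch_lists_offenders(self, small_model):
        weights = {"conv0.W": np.zeros((4, 4, 3, 3)), "conv1.W": np.zeros((2, 2))}
        with pytest.raises(WeightMismatchError) as err:
            make_backbone(small_preset(K=3), seed=1, weights=weights)
        assert "conv0" in str(err.value) and "conv1" in str(err.value)


class TestReplaceHead:
    def test_only_final_layer_changes(self, small_model):
        new = replace_head(small_model, 1, seed=2)
        assert new.K == 1
        assert parameter_checksum(new, exclude=("fc1",)) == parameter_checksum(
            small_model, exclude=("fc1",)
        )
        img = np.zeros((1, 64, 64, 3), dtype=np.uint8)
        assert new.scores(img).shape == (1, 1)

    def test_deterministic_and_idempotent_in_structure(self, small_model):
        a = replace_head(small_model, 1, seed=2)
        b = replace_head(small_model, 1, seed=2)
        assert parameter_checksum(a) == parameter_checksum(b)
        c = replace_head(a, 1, seed=2)
        assert [l.out_features for l in c.classifier] == [l.out_features for l in a.classifier]

    def test_invalid_K(self, small_model):
        with pytest.raises(ValueError):
            replace_head(small_model, 0)


class TestPruning:
    def test_zero_pruning_is_forward_identity(self, small_model):
        pruned = prune_conv_layers(small_model, 0)
        img = (np.arange(64 * 64 * 3) % 251).reshape(64, 64, 3).astype(np.uint8)
        assert np.array_equal(pruned.scores(img), small_model.scores(img))

    def test_structural_recount_matches(self):
        m = make_backbone(DEFAULT_CONFIG, seed=0)
        for n in (3, 12):
            pruned = prune_conv_layers(m, n, seed=1)
            assert pruned.depth == 13 - n  # independent recount of the layer list
            assert len(pruned.conv_layers) == sum(pruned.block_sizes)

    def test_pruned_forward_keeps_classifier_input_side(self, small_model):
        img = np.zeros((1, 64, 64, 3), dtype=np.uint8)
        for n in range(small_model.depth):
            pruned = prune_conv_layers(small_model, n, seed=1)
            assert pruned.scores(img).shape == (1, 3)
            side = pruned.pooled_features(img).shape[-1]
            assert side == small_model.config.pool_side

    def test_surviving_conv_parameters_unchanged(self, small_model):
        pruned = prune_conv_layers(small_model, 1, seed=1)
        for old, new in zip(small_model.conv_layers, pruned.conv_layers):
            assert np.array_equal(old.W.value, new.W.value)

    def test_excessive_pruning_rejected(self, small_model):
        with pytest.raises(ValueError):
            prune_conv_layers(small_model, small_model.depth)


class TestTrainability:
    def test_head_only_marks_exactly_final_layer(self):
        m = make_backbone(small_preset(K=3), seed=0)
        set_trainable(m, "head_only")
        trainable = m.n_parameters(trainable_only=True)
        last = m.classifier[-1]
        assert trainable == last.W.value.size + last.b.value.size

    def test_all_and_none(self):
        m = make_backbone(small_preset(K=3), seed=0)
        set_trainable(m, "all")
        assert m.n_parameters(trainable_only=True) == m.n_parameters()
        set_trainable(m, "none")
        assert m.n_parameters(trainable_only=True) == 0
        with pytest.raises(ValueError):
            set_trainable(m, "some")

    def test_frozen_parameters_survive_optimizer_steps(self):
        m = make_backbone(small_preset(K=3), seed=0)
        set_trainable(m, "none")
        before = parameter_checksum(m)
        opt = _nn.SGD(m.params(), lr=1.0, momentum=0.9)
        for p in m.params():
            p.add_grad(np.ones_like(p.value))
        opt.step()
        assert parameter_checksum(m) == before


class TestSerialization:
    def test_checkpoint_roundtrip(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(small_model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == small_model.config
        assert parameter_checksum(loaded) == parameter_checksum(small_model)


class TestEngineGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Spot-check analytic gradients against central differences."""
        rng = np.random.default_rng(0)
        m = make_backbone(
            BackboneConfig(channels=(4, 6), convs_per_block=(1, 1), pool_side=2,
                           hidden=(8,), K=2), seed=1,
        )
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1])

        for p in m.params():
            p.zero_grad()
        logits = m.forward(x, train=True)
        _, d = _nn.softmax_cross_entropy(logits, y)
        m.backward(d)

        for p in m.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-3, flat[idx]
                flat[idx] = old + eps
                up, _ = _nn.softmax_cross_entropy(m.forward(x), y)
                flat[idx] = old - eps
                dn, _ = _nn.softmax_cross_entropy(m.forward(x), y)
                flat[idx] = old
                # float32 forward passes limit central-difference precision
                assert grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=0.03, abs=3e-3)
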