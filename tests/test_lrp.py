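"""Layer-wise relevance propagation: hand-computed rules, conservation,
normalization, export, and the aorta-agreement surrogate."""

import json

import numpy as np
import pytest

from aaascreen import nn
from aaascreen.lrp import (
    RelevanceMap,
    UnsupportedLayerError,
    aorta_relevance_fraction,
    export_overlay,
    fold_batchnorm,
    normalize_map,
    relevance_map,
)
from aaascreen.models3d import ArchitectureSpec, Model, build_model
from aaascreen.preprocess import Patch
from aaascreen.volume import read_volume


def _bias_free_convnet(seed=0, shape=(8, 8, 8)):
    """conv-relu-pool-conv-relu-gap-linear with no biases or batch norm:
    the configuration in which the eps=0 rule is exactly conservative."""
    rng = np.random.default_rng(seed)
    net = nn.Sequential([
        nn.Conv3d(1, 4, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.ReLU(),
        nn.MaxPool3d(),
        nn.Conv3d(4, 6, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.ReLU(),
        nn.GlobalAvgPool3d(),
        nn.Linear(6, 2, bias=False, rng=rng),
    ])
    net.set_train(False)
    return Model(net, ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed)


class TestEpsilonRule:
    def test_single_linear_layer_matches_hand_computation(self):
        # y = w . x, no bias: relevance of input i is w_i * x_i
        lin = nn.Linear(3, 1, bias=False)
        lin.W = np.array([[2.0, -1.0, 0.5]], dtype=np.float32)
        net = nn.Sequential([lin])
        model = Model(net, ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), 0)
        x = np.array([1.0, 2.0, 4.0], dtype=np.float32)
        net.forward(x[None])
        from aaascreen.lrp import _prop_affine

        score = float(lin.forward(x[None])[0, 0])  # 2 - 2 + 2 = 2
        R = np.array([[score]])
        r_in = _prop_affine(lin, R, "epsilon", 0.0)[0]
        np.testing.assert_allclose(r_in, [2.0, -2.0, 2.0], atol=1e-6)

    def test_all_zero_input_gives_all_zero_map(self):
        model = _bias_free_convnet()
        rmap = relevance_map(model, Patch(np.zeros((8, 8, 8), dtype=np.float32)), epsilon=0.0)
        assert np.all(rmap.data == 0)

    def test_conservation_layer_by_layer_bias_free(self, rng):
        model = _bias_free_convnet(seed=3)
        patch = Patch(rng.uniform(-1, 1, (8, 8, 8)).astype(np.float32))
        rmap = relevance_map(model, patch, target_class=1, epsilon=0.0)
        for layer_sum in rmap.layer_sums:
            assert layer_sum == pytest.approx(rmap.score, abs=1e-4)
        assert rmap.data.sum() == pytest.approx(rmap.score, abs=1e-4)

    def test_scaling_input_scales_map_normalized_invariant(self, rng):
        model = _bias_free_convnet(seed=4)
        x = rng.uniform(0.1, 1, (8, 8, 8)).astype(np.float32)
        m1 = relevance_map(model, Patch(x), epsilon=0.0)
        m2 = relevance_map(model, Patch(2 * x), epsilon=0.0)
        # bias-free ReLU network is positively homogeneous of degree 1 in
        # its input, so relevance (score-seeded) scales by c^2... the map
        # normalized by its sum is invariant either way
        n1, n2 = normalize_map(m1), normalize_map(m2)
        np.testing.assert_allclose(n1.data, n2.data, atol=1e-6)

    def test_epsilon_rule_converges_to_exact_rule(self, rng):
        model = _bias_free_convnet(seed=5)
        patch = Patch(rng.uniform(0.2, 1, (8, 8, 8)).astype(np.float32))
        exact = relevance_map(model, patch, epsilon=0.0)
        for eps, tol in [(1e-2, 0.5), (1e-6, 1e-4)]:
            approx = relevance_map(model, patch, epsilon=eps)
            err = np.abs(approx.data - exact.data).max()
            assert err < tol

    def test_zplus_rule_yields_nonnegative_map_on_nonnegative_input(self, rng):
        model = _bias_free_convnet(seed=6)
        patch = Patch(rng.uniform(0, 1, (8, 8, 8)).astype(np.float32))
        rmap = relevance_map(model, patch, rule="zplus", epsilon=1e-9)
        assert rmap.data.min() >= -1e-6

    def test_unknown_rule_rejected(self, rng):
        model = _bias_free_convnet()
        with pytest.raises(ValueError, match="rule"):
            relevance_map(model, Patch(np.ones((8, 8, 8), dtype=np.float32)), rule="gamma")


class TestBatchNormFolding:
    def test_folded_network_is_inference_equivalent(self, rng):
        model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=2)
        # give BN non-trivial statistics
        for _, layer in nn.named_layers(model.net):
            if isinstance(layer, nn.BatchNorm3d):
                layer.running_mean = rng.normal(0, 0.3, layer.c).astype(np.float32)
                layer.running_var = rng.uniform(0.5, 2.0, layer.c).astype(np.float32)
                layer.gamma = rng.uniform(0.5, 1.5, layer.c).astype(np.float32)
                layer.beta = rng.normal(0, 0.1, layer.c).astype(np.float32)
        x = rng.uniform(-1, 1, (1, 1, 32, 32, 32)).astype(np.float32)
        folded = fold_batchnorm(model.net)
        folded.set_train(False)
        np.testing.assert_allclose(folded.forward(x), model.forward(x), atol=1e-3)
        assert not any(
            isinstance(layer, nn.BatchNorm3d) for _, layer in nn.named_layers(folded)
        )

    def test_resnet_relevance_map_runs_end_to_end(self, rng):
        model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=1)
        patch = Patch(rng.uniform(-1, 1, (32, 32, 32)).astype(np.float32))
        rmap = relevance_map(model, patch, target_class=1)
        assert rmap.shape == (32, 32, 32)
        assert np.isfinite(rmap.data).all()


class TestNormalize:
    def _map(self, data):
        return RelevanceMap(np.asarray(data, dtype=np.float64), 1, "epsilon")

    def test_sum_four_becomes_one(self):
        out = normalize_map(self._map([[[1.0, 1.0], [1.0, 1.0]]]))
        assert out.data.sum() == pytest.approx(1.0)
        assert out.normalized

    def test_idempotent(self):
        once = normalize_map(self._map(np.full((2, 2, 2), 0.5)))
        twice = normalize_map(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_zero_sum_rejected_input_untouched(self):
        m = self._map([[[1.0, -1.0]]])
        original = m.data.copy()
        with pytest.raises(ValueError, match="zero"):
            normalize_map(m)
        np.testing.assert_array_equal(m.data, original)

    def test_sign_pattern_preserved_for_positive_sum(self):
        m = self._map([[[3.0, -1.0], [2.0, 0.5]]])
        out = normalize_map(m)
        assert np.array_equal(np.sign(out.data), np.sign(m.data))


class TestExportAndFraction:
    def test_nifti_round_trip_and_overlay_count(self, rng, tmp_path):
        data = rng.normal(0, 1, (6, 6, 4))
        rmap = RelevanceMap(data, 1, "epsilon")
        patch = Patch(rng.uniform(-1, 1, (6, 6, 4)).astype(np.float32))
        files = export_overlay(rmap, patch, tmp_path)
        back = read_volume(tmp_path / files["nifti"])
        np.testing.assert_allclose(back.data, data.astype(np.float32), atol=0)
        assert len(files["slices"]) == 4
        legend = json.loads((tmp_path / "legend.json").read_text())
        assert legend["max_positive"] == "yellow"
        assert legend["max_negative"] == "light blue"

    def test_mask_covering_everything_gives_one(self, rng):
        rmap = RelevanceMap(rng.normal(0, 1, (4, 4, 4)), 1, "epsilon")
        assert aorta_relevance_fraction(rmap, np.ones((4, 4, 4), bool)) == pytest.approx(1.0)

    def test_all_zero_map_rejected(self):
        rmap = RelevanceMap(np.zeros((4, 4, 4)), 1, "epsilon")
        with pytest.raises(ValueError, match="zero"):
            aorta_relevance_fraction(rmap, np.ones((4, 4, 4), bool))

    def test_empty_mask_rejected(self, rng):
        rmap = RelevanceMap(rng.normal(0, 1, (4, 4, 4)), 1, "epsilon")
        with pytest.raises(ValueError, match="empty"):
            aorta_relevance_fraction(rmap, np.zeros((4, 4, 4), bool))

    def test_positive_and_negative_relevance_count_equally(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = -3.0  # negative relevance inside the mask
        data[3, 3, 3] = 1.0
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        rmap = RelevanceMap(data, 1, "epsilon")
        assert aorta_relevance_fraction(rmap, mask) == pytest.approx(0.75)
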