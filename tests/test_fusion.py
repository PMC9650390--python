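import numpy as np
import pytest

from legff.core import FusionConfig
from legff.decompose import decompose
from legff.fusion import (
    compute_weights,
    fuse_base,
    fuse_decompositions,
    fuse_feature_scale,
    fuse_pair,
    integrate_features,
    shannon_entropy,
    to_uint8,
)
from legff.synthetic import make_ct_like, make_mr_like


def equal_frequency_map(n_values: int) -> np.ndarray:
    """4x4 map hitting ``n_values`` distinct histogram bins equally often."""
    assert 16 % n_values == 0
    vals = np.linspace(0, 240, n_values)
    return np.repeat(vals, 16 // n_values).reshape(4, 4)


class TestFuseFeatureScale:
    def test_idempotent_on_identical_maps(self):
        b = np.abs(np.random.default_rng(0).normal(size=(6, 6)))
        d = -np.abs(np.random.default_rng(1).normal(size=(6, 6)))
        bf, df = fuse_feature_scale(b, b, d, d)
        assert np.array_equal(bf, b) and np.array_equal(df, d)

    def test_elementwise_max_and_min(self):
        bf, df = fuse_feature_scale(
            np.array([[3.0, 0.0]]), np.array([[1.0, 4.0]]),
            np.array([[-3.0, 0.0]]), np.array([[-1.0, -4.0]]),
        )
        assert np.array_equal(bf, [[3.0, 4.0]])
        assert np.array_equal(df, [[-3.0, -4.0]])


class TestShannonEntropy:
    def test_constant_image_zero_bits(self):
        assert shannon_entropy(np.full((8, 8), 17.0)) == 0.0

    def test_two_equal_bins_one_bit(self):
        img = np.zeros((4, 4))
        img[:2] = 255.0
        assert shannon_entropy(img) == pytest.approx(1.0)

    def test_four_equal_values_two_bits(self):
        assert shannon_entropy(equal_frequency_map(4)) == pytest.approx(2.0)

    def test_values_above_255_fold_into_top_bin(self):
        img = np.full((4, 4), 400.0)
        assert shannon_entropy(img) == 0.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([[-1.0]]))


class TestComputeWeights:
    def test_identical_maps_give_unit_weights(self):
        m = equal_frequency_map(4)
        assert compute_weights([m, m, m], "bright") == [1.0, 1.0, 1.0]

    def test_weights_are_entropies_over_minimum(self):
        maps = [equal_frequency_map(4), equal_frequency_map(16), equal_frequency_map(2)]
        # entropies are exactly [2, 4, 1] bits
        assert compute_weights(maps, "bright") == pytest.approx([2.0, 4.0, 1.0])

    def test_dark_maps_are_negated_before_entropy(self):
        maps = [-equal_frequency_map(4), -equal_frequency_map(2)]
        assert compute_weights(maps, "dark") == pytest.approx([2.0, 1.0])

    def test_zero_entropy_falls_back_to_unit_weights(self):
        maps = [np.zeros((4, 4)), equal_frequency_map(4)]
        assert compute_weights(maps, "bright") == [1.0, 1.0]

    def test_contract_on_real_decomposition(self):
        dec = decompose(make_mr_like(48, 3).image)
        w = compute_weights(dec.bright_maps, "bright")
        assert min(w) == 1.0 and all(x >= 1.0 for x in w)

    def test_bad_polarity_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([np.zeros((2, 2))], "sideways")


class TestIntegrateFeatures:
    def test_unit_weights_give_plain_sum(self):
        rng = np.random.default_rng(4)
        maps = [rng.uniform(0, 10, (5, 5)) for _ in range(3)]
        np.testing.assert_allclose(integrate_features(maps, [1, 1, 1]), sum(maps))

    def test_single_scale_scaling(self):
        m = np.ones((3, 3))
        np.testing.assert_allclose(integrate_features([m], [2.5]), 2.5 * m)

    def test_matches_loop_accumulation(self):
        rng = np.random.default_rng(5)
        maps = [rng.uniform(0, 10, (6, 6)) for _ in range(3)]
        weights = rng.uniform(1, 3, 3)
        expected = np.zeros((6, 6))
        for m, w in zip(maps, weights):
            expected += w * m
        np.testing.assert_allclose(integrate_features(maps, weights), expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_features([np.zeros((2, 2))], [1.0, 2.0])


class TestFuseBase:
    def test_elementwise_maximum(self):
        out = fuse_base(np.array([[10.0, 200.0]]), np.array([[50.0, 100.0]]))
        assert np.array_equal(out, [[50.0, 200.0]])

    def test_dominates_both_inputs(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(0, 255, (8, 8)), rng.uniform(0, 255, (8, 8))
        out = fuse_base(a, b)
        assert (out >= a).all() and (out >= b).all()


class TestFusePair:
    def test_self_fusion_identity_with_enhancement_off(self):
        img = make_mr_like(48, 7).image
        cfg = FusionConfig(enhance_weights=False)
        assert np.abs(fuse_pair(img, img, cfg) - img).max() < 1e-9

    def test_commutativity_bit_for_bit(self):
        a = make_ct_like(48, 8).image
        b = make_mr_like(48, 9).image
        assert np.array_equal(fuse_pair(a, b), fuse_pair(b, a))

    def test_zero_image_contributes_nothing(self):
        img2 = make_mr_like(32, 10).image
        cfg = FusionConfig(enhance_weights=False)
        zero = np.zeros((32, 32))
        dec2 = decompose(img2, cfg)
        out = fuse_decompositions(decompose(zero, cfg), dec2, cfg)
        np.testing.assert_array_equal(out["base"], np.maximum(dec2.base, 0.0))
        for fused_b, b2 in zip(out["bright_maps"], dec2.bright_maps):
            np.testing.assert_array_equal(fused_b, b2)

    def test_enhancement_never_reduces_detail_energy(self):
        a = make_ct_like(48, 11).image
        b = make_mr_like(48, 12).image
        on = fuse_decompositions(decompose(a), decompose(b), FusionConfig())
        off_cfg = FusionConfig(enhance_weights=False)
        off = fuse_decompositions(decompose(a), decompose(b), off_cfg)
        assert np.abs(on["bright"]).sum() >= np.abs(off["bright"]).sum()
        assert np.abs(on["dark"]).sum() >= np.abs(off["dark"]).sum()

    def test_fused_base_recoverable_as_max_of_bases(self):
        a = make_ct_like(32, 13).image
        b = make_mr_like(32, 14).image
        cfg = FusionConfig()
        out = fuse_decompositions(decompose(a, cfg), decompose(b, cfg), cfg)
        np.testing.assert_array_equal(
            out["base"], np.maximum(decompose(a, cfg).base, decompose(b, cfg).base)
        )


class TestToUint8:
    def test_clips_and_rounds_half_to_even(self):
        out = to_uint8(np.array([[-5.0, 0.5, 1.5, 300.0]]))
        assert np.array_equal(out, np.array([[0, 0, 2, 255]], dtype=np.uint8))
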