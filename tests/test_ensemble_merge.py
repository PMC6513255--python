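"""Tests for the AUC-weighted consensus, the home-range Gaussian blur and
the final combination rules."""

import math

import numpy as np
import pytest

from harpyrange.ensemble_merge import (
    BlurParams,
    combine_final,
    consensus_weighted,
    derive_blur_sd,
    gaussian_blur_map,
)
from harpyrange.environment import AlignmentError, RasterGrid
from harpyrange.sdm_models import SuitabilityMap

GT = (-60.0, 0.0, 0.008983111030542939, 0.008983111030542939)  # 1-km cells


def smap(values, provenance="test", nodata=-9999.0):
    return SuitabilityMap(
        grid=RasterGrid(np.asarray(values, float), GT, nodata=nodata),
        provenance=provenance,
    )


def const_map(value, shape=(16, 16)):
    return smap(np.full(shape, float(value)))


class TestConsensus:
    def test_identical_members_are_fixed_point(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(16, 16))
        cons = consensus_weighted({"a": smap(vals), "b": smap(vals.copy())},
                                  {"a": 0.8, "b": 0.9})
        np.testing.assert_allclose(cons.grid.grid.values, vals)

    def test_hand_weighted_average(self):
        cons = consensus_weighted(
            {"a": const_map(0.2), "b": const_map(0.8)}, {"a": 0.5, "b": 1.0}
        )
        np.testing.assert_allclose(cons.grid.grid.values, 0.6)

    def test_equal_weights_reduce_to_mean(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=(16, 16)), rng.uniform(size=(16, 16))
        cons = consensus_weighted({"a": smap(a), "b": smap(b)}, {"a": 0.7, "b": 0.7})
        np.testing.assert_allclose(cons.grid.grid.values, (a + b) / 2)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(2)
        members = {f"m{i}": smap(rng.uniform(size=(20, 20))) for i in range(5)}
        aucs = {f"m{i}": rng.uniform(0.5, 1.0) for i in range(5)}
        cons = consensus_weighted(members, aucs)
        lo = np.min([m.grid.values for m in members.values()], axis=0)
        hi = np.max([m.grid.values for m in members.values()], axis=0)
        assert (cons.grid.grid.values >= lo - 1e-12).all()
        assert (cons.grid.grid.values <= hi + 1e-12).all()

    def test_nodata_in_any_member_propagates(self):
        a = const_map(0.3)
        bvals = np.full((16, 16), 0.6)
        bvals[4, 5] = -9999.0
        cons = consensus_weighted({"a": a, "b": smap(bvals)}, {"a": 0.8, "b": 0.8})
        assert not cons.grid.grid.valid_mask()[4, 5]

    def test_mismatched_grids_rejected(self):
        other = SuitabilityMap(
            grid=RasterGrid(np.zeros((8, 8)), GT), provenance="x"
        )
        with pytest.raises(AlignmentError):
            consensus_weighted({"a": const_map(0.1), "b": other}, {"a": 0.9, "b": 0.9})


class TestDeriveBlurSd:
    def test_literal_mode_matches_printed_expression(self):
        params = derive_blur_sd("literal")
        assert params.sd_map_units == pytest.approx(25000.0 / 1.96, rel=1e-3)

    def test_home_range_mode_circle_radius(self):
        params = derive_blur_sd("home_range", home_range_km2=25.0)
        assert params.sd_map_units == pytest.approx(
            math.sqrt(25e6 / math.pi) / 1.96, rel=1e-3
        )

    def test_tighter_coverage_shrinks_sd(self):
        # as the coverage quantile approaches certainty, z grows and the
        # kernel SD tends to zero
        wide = derive_blur_sd("literal", coverage_quantile=0.95)
        tight = derive_blur_sd("literal", coverage_quantile=0.999999)
        assert tight.sd_map_units < wide.sd_map_units / 2

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            derive_blur_sd("fractal")


class TestGaussianBlur:
    def test_constant_map_unchanged(self):
        out = gaussian_blur_map(const_map(0.4), BlurParams(sd_map_units=3000.0))
        np.testing.assert_allclose(out.grid.values, 0.4, atol=1e-12)

    def test_impulse_response_matches_discrete_kernel(self):
        # center value of the blurred unit impulse equals the center
        # weight of the normalized discrete Gaussian kernel
        shape = (33, 33)
        vals = np.zeros(shape)
        vals[16, 16] = 1.0
        sd_cells = 2.0
        sd_m = sd_cells * 1000.0
        out = gaussian_blur_map(smap(vals), BlurParams(sd_map_units=sd_m))
        r = int(4.0 * sd_cells + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sd_cells**2))
        k1 /= k1.sum()
        k2 = np.outer(k1, k1)
        assert out.grid.values[16, 16] == pytest.approx(k2[r, r], rel=1e-6)
        # reflective boundary conserves total mass
        assert out.grid.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_preserved_on_fully_valid_grid(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=(24, 24))
        out = gaussian_blur_map(smap(vals), BlurParams(sd_map_units=5000.0))
        assert out.grid.values.mean() == pytest.approx(vals.mean(), abs=1e-6)

    def test_monotone_in_the_input(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(size=(20, 20))
        b = a + rng.uniform(0, 0.5, size=(20, 20))
        pa = gaussian_blur_map(smap(a), BlurParams(sd_map_units=4000.0))
        pb = gaussian_blur_map(smap(b), BlurParams(sd_map_units=4000.0))
        assert (pb.grid.values >= pa.grid.values - 1e-12).all()

    def test_range_contained_in_input_range(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.2, 0.9, size=(20, 20))
        out = gaussian_blur_map(smap(vals), BlurParams(sd_map_units=8000.0))
        assert out.grid.values.min() >= vals.min() - 1e-12
        assert out.grid.values.max() <= vals.max() + 1e-12

    def test_tiny_sd_is_identity_with_warning(self):
        vals = np.random.default_rng(6).uniform(size=(16, 16))
        with pytest.warns(UserWarning):
            out = gaussian_blur_map(smap(vals), BlurParams(sd_map_units=1e-9))
        np.testing.assert_array_equal(out.grid.values, vals)

    def test_nodata_aware_normalization(self):
        # a nodata hole must not drag neighbouring values toward zero
        vals = np.full((21, 21), 0.5)
        vals[10, 10] = -9999.0
        out = gaussian_blur_map(smap(vals), BlurParams(sd_map_units=2000.0))
        mask = out.grid.valid_mask()
        np.testing.assert_allclose(out.grid.values[mask], 0.5, atol=1e-9)
        assert not mask[10, 10]


class TestCombineFinal:
    def consensus_of(self, value):
        return consensus_weighted(
            {"a": const_map(value), "b": const_map(value)}, {"a": 0.9, "b": 0.9}
        )

    def test_unit_reproductive_map_is_identity(self):
        cons = self.consensus_of(0.37)
        out = combine_final(cons, const_map(1.0), "product")
        np.testing.assert_allclose(out.grid.values, 0.37)

    def test_zero_reproductive_map_annihilates(self):
        out = combine_final(self.consensus_of(0.8), const_map(0.0), "product")
        np.testing.assert_allclose(out.grid.values, 0.0)

    @pytest.mark.parametrize("rule,expected", [("product", 0.3), ("min", 0.5), ("mean", 0.55)])
    def test_rule_arithmetic(self, rule, expected):
        out = combine_final(self.consensus_of(0.6), const_map(0.5), rule)
        np.testing.assert_allclose(out.grid.values, expected)

    def test_product_bounded_by_each_input(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(size=(16, 16)), rng.uniform(size=(16, 16))
        cons = consensus_weighted({"a": smap(a), "b": smap(a.copy())}, {"a": 0.9, "b": 0.9})
        out = combine_final(cons, smap(b), "product")
        assert (out.grid.values <= a + 1e-12).all()
        assert (out.grid.values <= b + 1e-12).all()

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            combine_final(self.consensus_of(0.5), const_map(0.5), "median")
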