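"""Combining, independence check, masking, classification, distribution moments."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from foragescape import (
    ClassBreaks,
    apply_masks,
    classify,
    combine,
    correlation_matrix,
    distribution_summary,
)
from foragescape.suitability import CLASS_HIGH, CLASS_LOW, CLASS_MODERATE, MaskReason
from foragescape.variables import tri

from conftest import raster


def membership_triplet(a, b, c):
    return combine(raster(a), raster(b), raster(c))


class TestCorrelationMatrix:
    def test_identical_inputs_give_unit_correlation(self):
        a = raster(np.linspace(0, 1, 9).reshape(3, 3))
        m = correlation_matrix(a, a.with_values(a.values), a.with_values(a.values * 0.5))
        assert m == pytest.approx(np.ones((3, 3)))

    def test_complementary_inputs_give_minus_one(self):
        a = raster(np.linspace(0, 1, 9).reshape(3, 3))
        b = a.with_values(1 - a.values)
        m = correlation_matrix(a, b, a)
        assert m[0, 1] == pytest.approx(-1.0)

    def test_toy_pearson_matches_scipy(self):
        av = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        bv = np.array([[0.6, 0.4, 0.5], [0.2, 0.3, 0.1]])
        cv = np.array([[0.3, 0.1, 0.9], [0.2, 0.8, 0.4]])
        m = correlation_matrix(raster(av), raster(bv), raster(cv))
        assert m[0, 1] == pytest.approx(scipy.stats.pearsonr(av.ravel(), bv.ravel())[0])
        assert m[1, 2] == pytest.approx(scipy.stats.pearsonr(bv.ravel(), cv.ravel())[0])
        assert m == pytest.approx(m.T)  # symmetric, unit diagonal
        assert np.diag(m) == pytest.approx([1, 1, 1])

    def test_zero_variance_is_flagged_not_silent(self):
        a = raster(np.linspace(0, 1, 9).reshape(3, 3))
        const = a.with_values(np.full((3, 3), 0.5))
        with pytest.raises(ValueError, match="zero variance in var2"):
            correlation_matrix(a, const, a)

    def test_joint_validity_only(self):
        a = raster(np.array([[0.1, np.nan], [np.nan, 0.4]]))
        b = raster(np.array([[0.2, 0.8], [0.5, np.nan]]))
        with pytest.raises(ValueError, match="jointly valid"):
            correlation_matrix(a, b, a)  # a single jointly valid cell


class TestCombine:
    def test_equal_weight_mean(self):
        S = membership_triplet([[1.0]], [[0.5]], [[0.0]])
        assert S.S[0, 0] == pytest.approx(0.5)
        assert membership_triplet([[1.0]], [[1.0]], [[1.0]]).S[0, 0] == 1.0
        assert membership_triplet([[0.0]], [[0.0]], [[0.0]]).S[0, 0] == 0.0

    def test_custom_weights(self):
        S = combine(
            raster([[1.0]]), raster([[0.0]]), raster([[0.0]]), weights=(0.5, 0.25, 0.25)
        )
        assert S.S[0, 0] == pytest.approx(0.5)

    def test_weights_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex|summing"):
            combine(raster([[1.0]]), raster([[0.0]]), raster([[0.0]]), weights=(0.5, 0.5, 0.5))

    def test_membership_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            membership_triplet([[1.5]], [[0.5]], [[0.0]])

    def test_nodata_propagates(self):
        S = membership_triplet([[np.nan, 0.4]], [[0.5, 0.5]], [[0.0, 0.6]])
        assert np.isnan(S.S[0, 0])
        assert S.masked_reason[0, 0] == MaskReason.NODATA
        assert S.S[0, 1] == pytest.approx(0.5)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3))
    def test_permutation_invariant_and_bounded(self, vals):
        a, b, c = vals
        S1 = membership_triplet([[a]], [[b]], [[c]]).S[0, 0]
        S2 = membership_triplet([[c]], [[a]], [[b]]).S[0, 0]
        assert S1 == pytest.approx(S2)
        assert min(vals) - 1e-12 <= S1 <= max(vals) + 1e-12


class TestMasks:
    def _field(self):
        return membership_triplet(
            np.full((2, 3), 0.5), np.full((2, 3), 0.5), np.full((2, 3), 0.5)
        )

    def test_open_water_and_upland_cutoffs_are_strict(self):
        S = self._field()
        occ = raster(np.array([[80.0, 5.0, 0.0], [0.0, 0.0, 0.0]]))
        t = tri(raster(np.zeros((2, 3))))
        t.raster.values[:] = np.array([[0.0, 0.0, 0.0], [20.0, 17.0, 3.0]])
        out = apply_masks(S, occ, t)
        assert out.masked_reason[0, 0] == MaskReason.OPEN_WATER
        assert out.masked_reason[0, 1] == MaskReason.NONE  # 5.0 is not > 5.0
        assert out.masked_reason[1, 0] == MaskReason.MONTANE_UPLAND
        assert out.masked_reason[1, 1] == MaskReason.NONE  # 17 is not > 17
        assert out.unmasked.sum() == 4

    def test_masked_cells_leave_population(self):
        S = self._field()
        occ = raster(np.array([[80.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        t = tri(raster(np.zeros((2, 3))))
        out = apply_masks(S, occ, t)
        assert out.unmasked_values.size == 5


class TestClassify:
    def _breaks(self):
        return ClassBreaks(k=3, breaks=(0.710, 0.829), gvf=0.9, sample_size=100)

    def _field(self, vals):
        return membership_triplet(vals, vals, vals)

    def test_boundary_rule_upper_exclusive(self):
        S = self._field(np.array([[0.710, 0.711], [0.829, 0.830]]))
        cls = classify(S, self._breaks())
        assert cls.classes[0, 0] == CLASS_LOW       # exactly at b1 -> lower class
        assert cls.classes[0, 1] == CLASS_MODERATE
        assert cls.classes[1, 0] == CLASS_MODERATE  # exactly at b2 -> moderate
        assert cls.classes[1, 1] == CLASS_HIGH      # b2 + eps -> high

    def test_moderate_band_and_extremes(self):
        S = self._field(np.array([[0.0, 0.80], [1.0, 0.5]]))
        cls = classify(S, self._breaks())
        assert cls.classes[0, 0] == CLASS_LOW
        assert cls.classes[0, 1] == CLASS_MODERATE  # 0.80 between the breaks
        assert cls.classes[1, 0] == CLASS_HIGH
        assert cls.classes[1, 1] == CLASS_LOW

    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        S = self._field(rng.uniform(0, 1, size=(8, 8)))
        cls = classify(S, self._breaks())
        n = sum(cls.count(c) for c in (CLASS_LOW, CLASS_MODERATE, CLASS_HIGH))
        assert n == int(S.unmasked.sum())

    def test_breaks_outside_unit_interval_rejected(self):
        S = self._field(np.array([[0.5]]))
        bad = ClassBreaks(k=3, breaks=(0.5, 1.2), gvf=0.9, sample_size=10)
        with pytest.raises(ValueError, match="outside"):
            classify(S, bad)


class TestDistributionSummary:
    def test_hand_computed_moments(self):
        S = membership_triplet(*([np.array([[0.2, 0.4], [0.6, 0.8]])] * 3))
        d = distribution_summary(S)
        assert d["mean"] == pytest.approx(0.5)
        assert d["sd"] == pytest.approx(np.sqrt(0.05))
        assert d["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert d["n"] == 4

    def test_matches_scipy_skew(self):
        rng = np.random.default_rng(19)
        vals = rng.beta(5, 2, size=(6, 6))  # negatively skewed, like S
        S = membership_triplet(*([vals] * 3))
        d = distribution_summary(S)
        assert d["skewness"] == pytest.approx(scipy.stats.skew(vals.ravel()))
        assert d["skewness"] < 0

    def test_constant_field_flagged(self):
        S = membership_triplet(*([np.full((2, 2), 0.3)] * 3))
        d = distribution_summary(S)
        assert d["sd"] == 0.0 and np.isnan(d["skewness"])
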