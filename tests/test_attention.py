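"""Modulation indices, pooling, Wilcoxon/FDR, dominance, compartments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from laminargc.attention import (
    bh_mask, compartment_pool, dominance_matrix, modulation_index,
    pool_attend_out, repeated_measures_anova, smi, wilcoxon_fdr,
)
from laminargc.spectral import TimeFreqMap


class TestPooling:
    def test_equal_counts_pool_everything(self):
        pooled = pool_attend_out(np.arange(50), np.arange(100, 150), seed=0)
        assert pooled.size == 100
        assert (pooled < 50).sum() == 50

    def test_unequal_counts_subsample_to_minimum(self):
        pooled = pool_attend_out(np.arange(30), np.arange(100, 150), seed=0)
        assert pooled.size == 60
        assert (pooled < 30).sum() == 30

    def test_seeded_determinism(self):
        a = pool_attend_out(np.arange(40), np.arange(40, 90), seed=3)
        b = pool_attend_out(np.arange(40), np.arange(40, 90), seed=3)
        assert np.array_equal(a, b)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pool_attend_out(np.array([]), np.arange(5))


class TestModulationIndex:
    @pytest.mark.parametrize("rf,out,expected", [
        (1.0, 1.0, 0.0),
        (2.0, 1.0, 1.0 / 3.0),
        (3.0, 0.0, 1.0),
    ])
    def test_formula(self, rf, out, expected):
        assert modulation_index(rf, out) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        assert np.isnan(modulation_index(0.0, 0.0))

    @settings(deadline=None, max_examples=50)
    @given(hnp.arrays(np.float64, 6,
                      elements=st.floats(0.0, 1e6, allow_nan=False)),
           hnp.arrays(np.float64, 6,
                      elements=st.floats(0.0, 1e6, allow_nan=False)))
    def test_antisymmetry_and_range(self, a, b):
        mi = modulation_index(a, b)
        rev = modulation_index(b, a)
        defined = ~np.isnan(mi)
        assert np.array_equal(mi[defined], -rev[defined])
        assert (np.abs(mi[defined]) <= 1.0 + 1e-12).all()


class TestWilcoxonFDR:
    def test_bh_step_up_worked_example(self):
        """p = {0.01, 0.02, 0.03, 0.5} at q = 0.05: exactly 3 rejections."""
        mask = bh_mask([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert mask.sum() == 3 and not mask[3]

    def test_mirrored_samples_never_significant(self, rng):
        a = rng.standard_normal((4, 12))
        res = wilcoxon_fdr({"theta": (a, a.copy())})["theta"]
        assert not res["significant"].any()
        assert res["skipped"].all()      # all-zero differences are undefined

    def test_too_few_nontied_pairs_skipped(self, rng):
        d = np.zeros((1, 10))
        d[0, :3] = 1.0                   # only 3 non-tied pairs
        res = wilcoxon_fdr({"beta": d})["beta"]
        assert res["skipped"][0] and np.isnan(res["p"][0])

    def test_strong_consistent_effect_detected(self, rng):
        d = 1.0 + 0.1 * rng.standard_normal((3, 20))
        res = wilcoxon_fdr({"gamma": d})["gamma"]
        assert res["significant"].all()
        assert (res["q"] <= 0.05).all()


class TestDominance:
    def test_identical_directions_give_zero_matrix(self, rng):
        xy = rng.random((3, 10))
        dom = dominance_matrix(xy, xy.copy(), [(0, 1), (0, 2), (1, 2)], 3)
        assert not dom.matrix.any()

    def test_dominant_direction_sign_and_antisymmetry(self, rng):
        n_sess = 15
        xy = 1.0 + 0.05 * rng.random((1, n_sess))    # 0 -> 1 dominant
        yx = 0.2 + 0.05 * rng.random((1, n_sess))
        dom = dominance_matrix(xy, yx, [(0, 1)], 2)
        assert dom.matrix[0, 1] > 0
        assert dom.matrix[1, 0] == -dom.matrix[0, 1]

    def test_swapping_directions_flips_signs(self, rng):
        xy = 1.0 + 0.05 * rng.random((1, 15))
        yx = 0.2 + 0.05 * rng.random((1, 15))
        a = dominance_matrix(xy, yx, [(0, 1)], 2)
        b = dominance_matrix(yx, xy, [(0, 1)], 2)
        assert np.allclose(a.matrix, -b.matrix)


class TestNormalizeCGC:
    def test_band_values_normalized_to_group_maximum(self):
        from laminargc.attention import normalize_cgc
        out = normalize_cgc({"theta": 1.0, "alpha": 2.0, "beta": 4.0,
                             "low_gamma": 0.5, "high_gamma": 1.0})
        assert out["beta"] == 1.0
        assert out["theta"] == 0.25 and out["low_gamma"] == 0.125

    def test_single_band_maps_to_one(self):
        from laminargc.attention import normalize_cgc
        assert normalize_cgc({"beta": 3.0})["beta"] == 1.0

    def test_groups_normalized_independently(self):
        from laminargc.attention import normalize_cgc
        g1 = normalize_cgc({"theta": 2.0, "beta": 4.0})
        g2 = normalize_cgc({"theta": 10.0, "beta": 5.0})
        assert g1["beta"] == 1.0 and g2["theta"] == 1.0

    def test_zero_maximum_rejected(self):
        from laminargc.attention import normalize_cgc
        with pytest.raises(ValueError, match="zero"):
            normalize_cgc({"theta": 0.0, "beta": 0.0})


class TestCompartmentPool:
    COMP = np.array(["supragranular", "granular", "granular", "infragranular",
                     "unassigned"])

    def test_constant_values_give_constant_cells(self):
        pairs = [(0, 1), (1, 0), (1, 3), (3, 2), (0, 3), (3, 0)]
        with pytest.warns(UserWarning, match="empty"):
            pooled = compartment_pool(np.full(len(pairs), 2.5), pairs, self.COMP)
        assert np.allclose(pooled[np.isfinite(pooled)], 2.5)

    def test_unassigned_contacts_excluded(self):
        pairs = [(0, 4), (4, 1), (0, 1)]
        with pytest.warns(UserWarning, match="empty"):
            pooled = compartment_pool(np.array([100.0, 100.0, 1.0]), pairs,
                                      self.COMP)
        assert pooled[0, 1] == 1.0       # only the (supra, gran) pair counts

    def test_effect_confined_to_one_cell_is_largest_there(self):
        pairs = [(1, 0), (2, 0), (0, 1), (3, 1), (1, 3)]
        vals = np.array([5.0, 5.0, 0.1, 0.1, 0.1])   # granular -> supra strong
        with pytest.warns(UserWarning, match="empty"):
            pooled = compartment_pool(vals, pairs, self.COMP)
        assert np.nanargmax(pooled) == np.ravel_multi_index((1, 0), (3, 3))


class TestSMI:
    def make_map(self, values):
        return TimeFreqMap(times_ms=np.arange(values.shape[0], dtype=float),
                           freqs=np.arange(values.shape[2], dtype=float),
                           values=values, window_samples=128, step_ms=20.0)

    def test_identical_maps_give_zero_smi(self, rng):
        v = rng.random((26, 2, 10)) + 0.1
        out = smi(self.make_map(v), self.make_map(v.copy()))
        assert np.allclose(out.values, 0.0)
        assert out.values.shape[0] == 26     # grid preserved

    def test_grid_mismatch_rejected(self, rng):
        a = self.make_map(rng.random((5, 2, 10)))
        b = self.make_map(rng.random((6, 2, 10)))
        with pytest.raises(ValueError, match="grids"):
            smi(a, b)


def test_repeated_measures_anova_detects_condition_effect(rng):
    null = rng.standard_normal((3, 15))
    effect = null.copy()
    effect[0] += 2.0
    assert repeated_measures_anova(null) > 0.05
    assert repeated_measures_anova(effect) < 0.001
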