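import itertools

import numpy as np
import pytest

from cropsuit.change import (
    delta_suitability,
    ensemble_change,
    marginal_suitability_mask,
    member_significance,
    regional_summary,
    robustness,
    sign_agreement,
)
from cropsuit.climate_io import DEFAULT_REGIONS, RegionDefinition


def welch_t(x, y):
    """Textbook Welch statistic, written independently of scipy."""
    nx, ny = len(x), len(y)
    vx = np.var(x, ddof=1) / nx
    vy = np.var(y, ddof=1) / ny
    return (np.mean(x) - np.mean(y)) / np.sqrt(vx + vy)


class TestDelta:
    def test_identical_periods_give_zero(self, rng):
        base = rng.uniform(0, 1, (5, 4, 6))
        np.testing.assert_array_equal(delta_suitability(base, base), 0.0)

    def test_uniform_shift(self, rng):
        base = rng.uniform(0, 0.8, (5, 4, 6))
        np.testing.assert_allclose(
            delta_suitability(base, base + 0.1), 0.1, atol=1e-15
        )

    def test_single_cell_manual_subtraction(self, rng):
        base = rng.uniform(0, 1, (3, 2, 2))
        fut = rng.uniform(0, 1, (3, 2, 2))
        d = delta_suitability(base, fut)
        assert d[1, 0, 1] == fut[1, 0, 1] - base[1, 0, 1]

    def test_member_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_suitability(np.zeros((3, 2, 2)), np.zeros((4, 2, 2)))

    def test_nan_propagates(self):
        base = np.zeros((2, 1, 1))
        fut = np.full((2, 1, 1), np.nan)
        assert np.isnan(delta_suitability(base, fut)).all()


class TestSignAgreement:
    def test_all_positive_is_full_agreement(self):
        deltas = np.abs(np.random.default_rng(0).normal(size=(10, 3, 3))) + 0.01
        np.testing.assert_array_equal(sign_agreement(deltas), 1.0)

    def test_eight_of_ten_positive(self):
        deltas = np.ones((10, 1, 1))
        deltas[8:] = -0.1  # mean stays positive
        assert sign_agreement(deltas)[0, 0] == pytest.approx(0.8)

    def test_zero_deltas_agree_with_either_sign(self):
        deltas = np.ones((10, 1, 1))
        deltas[7:] = 0.0
        assert sign_agreement(deltas)[0, 0] == pytest.approx(1.0)

    def test_zero_mean_counts_zero_deltas(self):
        deltas = np.zeros((4, 1, 1))
        deltas[0], deltas[1] = 1.0, -1.0  # mean exactly zero, 2 of 4 zero
        assert sign_agreement(deltas)[0, 0] == pytest.approx(0.5)

    def test_needs_two_members(self):
        with pytest.raises(ValueError):
            sign_agreement(np.ones((1, 2, 2)))

    def test_identical_members_nonzero_delta(self, rng):
        d = rng.normal(size=(1, 3, 3)).repeat(6, axis=0) + 2.0
        np.testing.assert_array_equal(sign_agreement(d), 1.0)


class TestSignificance:
    def test_identical_samples_not_significant(self):
        x = np.tile(np.linspace(0, 1, 30), (2, 1))[:, :, None, None]
        sig = member_significance(x, x.copy())
        assert not sig.any()

    def test_constant_equal_samples_p_one_convention(self):
        x = np.full((1, 30, 1, 1), 0.4)
        assert not member_significance(x, x.copy()).any()

    def test_five_sd_effect_power_is_one(self, rng):
        """Mean shift of 5 pooled SDs with n=30 is detected essentially always."""
        base = rng.normal(0.3, 0.02, size=(10, 30, 4, 4))
        fut = rng.normal(0.3 + 5 * 0.02, 0.02, size=(10, 30, 4, 4))
        sig = member_significance(base, fut)
        assert sig.mean() == pytest.approx(1.0, abs=0.005)

    def test_t_statistic_matches_textbook_formula(self):
        """Fixed 5-value toy samples against a hand-computed Welch statistic."""
        from scipy import stats

        x = np.array([0.31, 0.35, 0.29, 0.40, 0.33])
        y = np.array([0.52, 0.47, 0.55, 0.49, 0.50])
        res = stats.ttest_ind(y, x, equal_var=False)
        assert res.statistic == pytest.approx(welch_t(y, x), abs=1e-10)
        # and the decision surface agrees with a manual p threshold
        a = x[None, :, None, None]
        b = y[None, :, None, None]
        assert member_significance(a, b, alpha=0.01)[0, 0, 0]

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            member_significance(np.zeros((2, 30, 1, 1)), np.zeros((2, 29, 1, 1)))


class TestRobustness:
    @pytest.mark.parametrize(
        "agree, sig, expected",
        [(0.9, 0.9, True), (0.7, 1.0, False), (1.0, 0.7, False),
         (0.8, 0.8, True), (0.79, 0.9, False)],
    )
    def test_two_condition_rule(self, agree, sig, expected):
        assert bool(robustness(np.array(agree), np.array(sig))) is expected

    def test_enumeration_over_ten_member_sign_patterns(self):
        """For every sign pattern of a 10-member ensemble the classifier
        agrees with direct counting of majority-sign members."""
        for bits in itertools.product([1.0, -1.0], repeat=10):
            deltas = np.array(bits)[:, None, None] * 0.2
            frac = sign_agreement(deltas)[0, 0]
            mean = deltas.mean()
            n_agree = sum(1 for b in bits if np.sign(b * 0.2) == np.sign(mean))
            if mean == 0:
                n_agree = 0  # no zero deltas in this construction
            assert frac == pytest.approx(n_agree / 10)
            for sig_frac in (0.7, 0.8, 0.9):
                expected = bool(frac >= 0.8) and bool(sig_frac >= 0.8)
                assert bool(robustness(np.array(frac), np.array(sig_frac))) is expected

    def test_robust_implies_both_fractions(self, rng):
        agree = rng.uniform(0, 1, (20, 20))
        sig = rng.uniform(0, 1, (20, 20))
        rob = robustness(agree, sig)
        assert np.all(agree[rob] >= 0.8)
        assert np.all(sig[rob] >= 0.8)


class TestMarginalMask:
    @pytest.mark.parametrize(
        "siv, inside",
        [(0.50, True), (0.41, True), (0.59, True), (0.60, False),
         (0.40, False), (0.0, False), (1.0, False)],
    )
    def test_band_bounds(self, siv, inside):
        assert bool(marginal_suitability_mask(np.array(siv))) is inside


class TestRegionalSummary:
    def test_uniform_field_mean_is_constant(self):
        lats = np.arange(2.25, 20, 0.5)
        field = np.full((lats.size, 8), 0.42)
        out = regional_summary(field, lats, DEFAULT_REGIONS)
        np.testing.assert_allclose(out["mean"], 0.42, atol=1e-12)
        assert set(out["region"]) == {"Guinea", "Savanna", "Sahel"}
        assert (out["Marginally suitable"] == out["n_cells"]).all()

    def test_single_cell_region(self):
        lats = np.array([5.0, 15.0])
        field = np.array([[0.9], [0.1]])
        out = regional_summary(
            field, lats, [RegionDefinition("south", 4.0, 6.0, -20, 20)]
        )
        assert out["mean"].iloc[0] == pytest.approx(0.9)

    def test_weights_match_manual_cosine_sum(self, rng):
        lats = np.arange(4.25, 20, 0.5)
        field = rng.uniform(0, 1, (lats.size, 6))
        out = regional_summary(field, lats, DEFAULT_REGIONS).set_index("region")
        for region in DEFAULT_REGIONS:
            sel = (lats >= region.lat_min) & (lats < region.lat_max)
            w = np.cos(np.deg2rad(lats[sel]))[:, None] * np.ones((1, 6))
            manual = (field[sel] * w).sum() / w.sum()
            assert out.loc[region.name, "mean"] == pytest.approx(manual, abs=1e-12)

    def test_empty_region_is_an_error(self):
        lats = np.array([5.0])
        with pytest.raises(ValueError, match="empty"):
            regional_summary(
                np.zeros((1, 2)), lats, [RegionDefinition("north", 15.0, 18.0)]
            )


def test_ensemble_change_assembles_consistently(rng):
    """End-to-end: a strong uniform increase is robust everywhere."""
    base_ann = rng.normal(0.3, 0.02, size=(10, 30, 5, 5))
    fut_ann = base_ann + 0.2
    base = base_ann.mean(axis=1)
    fut = fut_ann.mean(axis=1)
    ecf = ensemble_change(
        baseline_window_siv=base, gwl_window_siv=fut,
        baseline_annual=base_ann, gwl_annual=fut_ann,
        lats=np.arange(5), lons=np.arange(5), level=2.0, crop_name="maize",
    )
    np.testing.assert_allclose(ecf.ensemble_mean_delta, 0.2, atol=1e-12)
    assert ecf.robust.all()
    assert ecf.agreement_fraction.min() == 1.0
    assert ecf.significant_fraction.min() == 1.0
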