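import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropsuit.ecocrop import (
    classify_siv,
    compute_suitability,
    compute_suitability_cube,
    monthly_temperature_suitability,
    season_suitability,
    trapezoid_suitability,
)
from tests.conftest import make_uniform_climatology


def reference_trapezoid(x, a, b, c, d):
    """Independent closed-form piecewise evaluation."""
    if b <= x <= c:
        return 1.0
    if x <= a or x >= d:
        return 0.0
    if x < b:
        return (x - a) / (b - a)
    return (d - x) / (d - c)


class TestTrapezoid:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (20.0, 1.0),   # lower optimum
            (30.0, 1.0),   # upper optimum
            (25.0, 1.0),   # plateau interior
            (10.0, 0.0),   # absolute minimum
            (40.0, 0.0),   # absolute maximum
            (15.0, 0.5),   # lower shoulder midpoint
            (35.0, 0.5),   # upper shoulder midpoint
            (12.5, 0.25),
            (37.5, 0.25),
            (5.0, 0.0),
            (45.0, 0.0),
        ],
    )
    def test_closed_form_values(self, x, expected):
        assert trapezoid_suitability(x, 10, 20, 30, 40) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(-50, 100))
    def test_matches_reference_everywhere(self, x):
        got = trapezoid_suitability(x, 10.0, 20.0, 30.0, 40.0)
        assert got == pytest.approx(reference_trapezoid(x, 10, 20, 30, 40), abs=1e-12)
        assert 0.0 <= got <= 1.0

    def test_degenerate_shoulders_plateau_wins(self):
        # zero-width lower shoulder: value at the shared bound is optimal
        assert trapezoid_suitability(10.0, 10, 10, 30, 40) == 1.0
        assert trapezoid_suitability(30.0, 10, 20, 30, 30) == 1.0
        # fully degenerate: indicator of the single point
        assert trapezoid_suitability(5.0, 5, 5, 5, 5) == 1.0
        assert trapezoid_suitability(5.1, 5, 5, 5, 5) == 0.0

    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValueError, match="unordered"):
            trapezoid_suitability(25.0, 10, 30, 20, 40)

    def test_vectorised_matches_scalar(self, rng):
        xs = rng.uniform(-10, 60, 100)
        vec = trapezoid_suitability(xs, 10, 20, 30, 40)
        scalars = [trapezoid_suitability(float(x), 10, 20, 30, 40) for x in xs]
        np.testing.assert_allclose(vec, scalars, atol=1e-15)

    def test_nan_propagates(self):
        assert np.isnan(trapezoid_suitability(np.nan, 10, 20, 30, 40))


class TestMonthlyTemperature:
    def test_kill_rule_overrides_optimal_mean(self, simple_crop):
        assert monthly_temperature_suitability(-1.0, 25.0, simple_crop) == 0.0
        assert monthly_temperature_suitability(0.0, 25.0, simple_crop) == 0.0  # at ktmp

    def test_optimal_when_above_kill(self, simple_crop):
        assert monthly_temperature_suitability(5.0, 25.0, simple_crop) == 1.0

    def test_lower_shoulder_midpoint(self, simple_crop):
        assert monthly_temperature_suitability(5.0, 15.0, simple_crop) == pytest.approx(0.5)


class TestSeason:
    def test_product_of_factors(self, simple_crop):
        """Tsuit 0.8 (limiting month on the shoulder) x Rsuit 0.5."""
        tmean = np.full(12, 25.0)
        tmean[2] = 18.0  # score 0.8 on the lower shoulder; min over season
        prec = np.full(12, 200.0 / 3)  # season total 200 -> Rsuit 0.5
        suit = season_suitability(np.full(12, 5.0), tmean, prec, 1, simple_crop)
        assert suit == pytest.approx(0.8 * 0.5, abs=1e-12)

    def test_uniform_climate_start_independent(self, simple_crop):
        tmin, tmean, prec = np.full(12, 5.0), np.full(12, 25.0), np.full(12, 120.0)
        vals = [
            season_suitability(tmin, tmean, prec, i, simple_crop) for i in range(1, 13)
        ]
        assert len(set(np.round(vals, 15))) == 1

    def test_fully_optimal_gives_one(self, simple_crop):
        suit = season_suitability(
            np.full(12, 5.0), np.full(12, 25.0), np.full(12, 150.0), 6, simple_crop
        )
        assert suit == 1.0

    def test_december_wraparound(self, simple_crop):
        """A start in November uses Nov, Dec, Jan for a 3-month season."""
        prec = np.zeros(12)
        prec[[10, 11, 0]] = 150.0  # optimal total only for the Nov start
        tmin, tmean = np.full(12, 5.0), np.full(12, 25.0)
        assert season_suitability(tmin, tmean, prec, 11, simple_crop) == 1.0
        assert season_suitability(tmin, tmean, prec, 2, simple_crop) == 0.0

    def test_bad_start_month(self, simple_crop):
        with pytest.raises(ValueError):
            season_suitability(
                np.zeros(12), np.zeros(12), np.zeros(12), 13, simple_crop
            )


class TestCube:
    def test_all_optimal_uniform_climate_is_identically_one(self, simple_crop):
        clim = make_uniform_climatology(tmin=5.0, tmean=25.0, prec=150.0)
        cube = compute_suitability_cube(clim, simple_crop)
        np.testing.assert_array_equal(cube.suit, 1.0)

    def test_zero_rain_with_positive_requirement_is_zero(self, simple_crop):
        clim = make_uniform_climatology(tmin=5.0, tmean=25.0, prec=0.0)
        cube = compute_suitability_cube(clim, simple_crop)
        np.testing.assert_array_equal(cube.suit, 0.0)

    def test_one_cell_matches_twelve_direct_calls(self, simple_crop, rng):
        clim = make_uniform_climatology()
        clim.tmean = rng.uniform(10, 40, clim.tmean.shape)
        clim.tmin = clim.tmean - 8.0
        clim.prec = rng.uniform(0, 300, clim.prec.shape)
        cube = compute_suitability_cube(clim, simple_crop)
        i, j = 2, 3
        direct = [
            season_suitability(
                clim.tmin[i, j], clim.tmean[i, j], clim.prec[i, j], s, simple_crop
            )
            for s in range(1, 13)
        ]
        np.testing.assert_allclose(cube.suit[i, j], direct, atol=1e-14)

    def test_masked_cells_are_nan(self, simple_crop):
        clim = make_uniform_climatology(tmin=5.0, tmean=25.0, prec=150.0)
        clim.mask[1, 1] = False
        cube = compute_suitability_cube(clim, simple_crop)
        assert np.isnan(cube.suit[1, 1]).all()
        assert (cube.suit[cube.mask] == 1.0).all()

    def test_rotation_equivariance(self, simple_crop, rng):
        """Rotating the monthly climate by k months rotates the start axis."""
        clim = make_uniform_climatology()
        clim.tmean = rng.uniform(10, 40, clim.tmean.shape)
        clim.tmin = clim.tmean - 8.0
        clim.prec = rng.uniform(0, 300, clim.prec.shape)
        base = compute_suitability_cube(clim, simple_crop).suit
        for k in (1, 3, 7):
            rot = make_uniform_climatology()
            rot.tmean = np.roll(clim.tmean, k, axis=-1)
            rot.tmin = np.roll(clim.tmin, k, axis=-1)
            rot.prec = np.roll(clim.prec, k, axis=-1)
            rotated = compute_suitability_cube(rot, simple_crop).suit
            np.testing.assert_allclose(rotated, np.roll(base, k, axis=-1), atol=1e-14)

    def test_kill_in_any_season_month_zeroes_suit(self, simple_crop):
        clim = make_uniform_climatology(tmin=5.0, tmean=25.0, prec=150.0)
        clim.tmin[0, 0, 5] = -2.0  # June frost
        cube = compute_suitability_cube(clim, simple_crop)
        # starts 4, 5, 6 (Apr, May, Jun) include June for a 3-month season
        assert cube.suit[0, 0, 3] == 0.0
        assert cube.suit[0, 0, 4] == 0.0
        assert cube.suit[0, 0, 5] == 0.0
        assert cube.suit[0, 0, 6] == 1.0

    def test_suit_bounded_by_both_factors(self, simple_crop, rng):
        """SUIT_i <= Tsuit_i and SUIT_i <= Rsuit_i, and monotone in rain score."""
        tmin = rng.uniform(-2, 20, (50, 12))
        tmean = tmin + rng.uniform(0, 15, (50, 12))
        prec = rng.uniform(0, 400, (50, 12))
        suit = compute_suitability(tmin, tmean, prec, simple_crop)
        assert np.all(suit >= 0) and np.all(suit <= 1)
        monthly = monthly_temperature_suitability(tmin, tmean, simple_crop)
        for start in range(12):
            idx = (start + np.arange(simple_crop.season_length)) % 12
            tsuit = monthly[:, idx].min(axis=1)
            rsuit = trapezoid_suitability(
                prec[:, idx].sum(axis=1), 100, 300, 600, 1000
            )
            assert np.all(suit[:, start] <= tsuit + 1e-12)
            assert np.all(suit[:, start] <= rsuit + 1e-12)
            np.testing.assert_allclose(suit[:, start], tsuit * rsuit, atol=1e-12)

    def test_season_length_twelve_uses_whole_year(self, simple_crop):
        crop = dataclasses.replace(
            simple_crop, season_length=12, r_opt_min=1200.0, r_opt_max=2400.0,
            r_abs_min=400.0, r_abs_max=4000.0,
        )
        clim = make_uniform_climatology(tmin=5.0, tmean=25.0, prec=150.0)
        cube = compute_suitability_cube(clim, crop)
        np.testing.assert_allclose(cube.suit, 1.0)


class TestCategories:
    @pytest.mark.parametrize(
        "siv, label",
        [
            (0.10, "Unsuitable"),
            (0.20, "Unsuitable"),
            (0.21, "Very Marginally suitable"),
            (0.40, "Very Marginally suitable"),
            (0.50, "Marginally suitable"),
            (0.60, "Marginally suitable"),
            (0.70, "Suitable"),
            (0.80, "Suitable"),
            (0.81, "Highly suitable"),
            (0.90, "Highly suitable"),
            (1.00, "Highly suitable"),
            (0.00, "Unsuitable"),
        ],
    )
    def test_category_bounds(self, siv, label):
        assert classify_siv(siv) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_siv(1.5)
        with pytest.raises(ValueError):
            classify_siv(-0.1)

    def test_vectorised_with_nan(self):
        out = classify_siv(np.array([0.1, np.nan, 0.9]))
        assert out[0] == "Unsuitable" and out[2] == "Highly suitable"
        assert out[1] is None
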