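import datetime as dt

import numpy as np
import pytest

from wheatcast.raster import GridSpec, RasterCube
from wheatcast.reconstruct import (
    SGParams,
    SeasonSpec,
    fuse,
    monthly_max_composite,
    sg_smooth,
    temporal_interpolate,
)

SPEC1 = GridSpec(0, 1, 1, 1, 1, 1, "t")


def one_pixel_cube(series, valid=None, dates=None):
    values = np.asarray(series, float).reshape(-1, 1, 1)
    if valid is None:
        valid = np.isfinite(values)
        values = np.nan_to_num(values)
    else:
        valid = np.asarray(valid, bool).reshape(-1, 1, 1)
    if dates is None:
        dates = [dt.date(2019, 10, 15) + dt.timedelta(days=31 * i) for i in range(values.shape[0])]
    return RasterCube.from_arrays(SPEC1, dates, values, valid)


def slot_cube(series, valid=None, harvest_year=2020):
    return one_pixel_cube(series, valid, dates=SeasonSpec(harvest_year).slot_dates)


class TestSeasonSpec:
    def test_eight_slots_october_to_may(self):
        slots = SeasonSpec(2020).slots
        assert len(slots) == 8
        assert slots[0] == (2019, 10) and slots[3] == (2020, 1) and slots[-1] == (2020, 5)
        assert SeasonSpec(2020).slot_dates[0] == dt.date(2019, 10, 15)


class TestMonthlyMaxComposite:
    def test_takes_max_order_invariant_and_empty_slot(self):
        dates = [dt.date(2020, 3, d) for d in (1, 10, 20)] + [dt.date(2020, 4, 2)]
        for perm in ([0, 1, 2, 3], [2, 0, 1, 3]):
            vals = np.array([0.2, 0.5, 0.3, 0.4])[perm].reshape(-1, 1, 1)
            order = np.argsort([dates[i].toordinal() for i in perm])
            cube = RasterCube.from_arrays(
                SPEC1, [dates[perm[i]] for i in order], vals[order]
            )
            out = monthly_max_composite(cube, SeasonSpec(2020))
            assert out.layers[5].values[0, 0] == pytest.approx(0.5)  # March max
            assert out.layers[6].values[0, 0] == pytest.approx(0.4)  # April singleton
            assert not out.layers[2].valid[0, 0]  # December: no observation
            assert len(out) == 8

    def test_invalid_observations_ignored(self):
        dates = [dt.date(2019, 10, d) for d in (5, 15)]
        cube = RasterCube.from_arrays(
            SPEC1, dates, np.array([0.9, 0.4]).reshape(-1, 1, 1),
            np.array([False, True]).reshape(-1, 1, 1),
        )
        out = monthly_max_composite(cube, SeasonSpec(2020))
        assert out.layers[0].values[0, 0] == pytest.approx(0.4)

    def test_outside_season_raises(self):
        cube = one_pixel_cube([0.1], dates=[dt.date(2020, 7, 1)])
        with pytest.raises(ValueError):
            monthly_max_composite(cube, SeasonSpec(2020))


class TestTemporalInterpolate:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([1, np.nan, 3], [1, 2, 3]),          # interior linear fill
            ([np.nan, 2, 4], [2, 2, 4]),          # leading nearest-value fill
            ([1, 2, 4, np.nan], [1, 2, 4, 4]),    # trailing nearest-value fill
            ([1, 2, 3], [1, 2, 3]),               # fully valid: identity
            ([np.nan, 1, np.nan, np.nan, 5, np.nan], [1, 1, 7 / 3, 11 / 3, 5, 5]),
        ],
    )
    def test_series(self, series, expected):
        out = temporal_interpolate(one_pixel_cube(series))
        np.testing.assert_allclose(out.values_array().ravel(), expected)
        assert out.valid_array().all()

    def test_all_invalid_pixel_stays_invalid(self):
        out = temporal_interpolate(one_pixel_cube([np.nan, np.nan, np.nan]))
        assert not out.valid_array().any()

    def test_reproduces_valid_entries_exactly(self, rng):
        spec = GridSpec(0, 6, 1, 1, 6, 6, "t")
        vals = rng.random((8, 6, 6))
        ok = rng.random((8, 6, 6)) > 0.4
        dates = SeasonSpec(2020).slot_dates
        cube = RasterCube.from_arrays(spec, dates, np.where(ok, vals, 0.0), ok)
        out = temporal_interpolate(cube)
        np.testing.assert_allclose(out.values_array()[ok], vals[ok])
        n_valid = ok.sum(axis=0)
        assert out.valid_array().sum(axis=0)[n_valid > 0].min() == 8


def sg_oracle(series, window, polyorder):
    """Independent SG oracle: per-position least-squares polynomial fit,
    with the edge policy of fitting the first/last full window."""
    n = len(series)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        t = np.arange(lo, lo + window)
        coeffs = np.polyfit(t, series[lo : lo + window], polyorder)
        out[i] = np.polyval(coeffs, i)
    return out


class TestSgSmooth:
    def test_constant_series_unchanged(self):
        out = sg_smooth(slot_cube([5.0] * 8), SGParams(5, 2))
        np.testing.assert_allclose(out.values_array().ravel(), [5.0] * 8, atol=1e-12)

    def test_quadratic_reproduced_everywhere(self):
        series = np.arange(8, dtype=float) ** 2
        out = sg_smooth(slot_cube(series), SGParams(5, 2))
        np.testing.assert_allclose(out.values_array().ravel(), series, atol=1e-9)

    def test_impulse_center_weight_is_17_over_35(self):
        series = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0, 0, 0])
        out = sg_smooth(slot_cube(series), SGParams(5, 2))
        assert out.values_array().ravel()[2] == pytest.approx(17 / 35, abs=1e-12)

    def test_matches_least_squares_oracle_on_random_series(self, rng):
        series = rng.random(8)
        out = sg_smooth(slot_cube(series), SGParams(5, 2))
        np.testing.assert_allclose(out.values_array().ravel(), sg_oracle(series, 5, 2), atol=1e-9)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            sg_smooth(slot_cube([1.0] * 8), SGParams(9, 2))

    def test_gappy_cube_rejected(self):
        cube = slot_cube([1, 2, np.nan, 4, 5, 6, 7, 8])
        with pytest.raises(ValueError):
            sg_smooth(cube, SGParams(5, 2))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SGParams(4, 2)
        with pytest.raises(ValueError):
            SGParams(5, 5)


class TestFuse:
    def fine_coarse(self, fine_series, fine_valid):
        fine = slot_cube(fine_series, fine_valid)
        coarse = slot_cube(np.linspace(0.1, 0.8, 8))
        return fine, coarse

    def test_fully_valid_fine_equals_smoothed_fine(self):
        series = np.linspace(0.1, 0.8, 8)
        fine, coarse = self.fine_coarse(series, [True] * 8)
        result = fuse(fine, coarse, SGParams(5, 2))
        np.testing.assert_allclose(
            result.smoothed.values_array(), sg_smooth(fine, SGParams(5, 2)).values_array()
        )
        assert (result.source == 1).all()

    def test_fully_invalid_fine_takes_coarse_path(self):
        fine, coarse = self.fine_coarse([0.0] * 8, [False] * 8)
        result = fuse(fine, coarse, SGParams(5, 2))
        np.testing.assert_allclose(
            result.smoothed.values_array(), sg_smooth(coarse, SGParams(5, 2)).values_array()
        )
        assert (result.source == 2).all()

    def test_gap_slots_take_coarse_before_smoothing(self):
        series = np.linspace(0.1, 0.8, 8)
        valid = np.array([True] * 8)
        valid[[2, 5]] = False
        fine, coarse = self.fine_coarse(series, valid)
        result = fuse(fine, coarse, SGParams(5, 2))
        filled = result.filled.values_array().ravel()
        coarse_vals = coarse.values_array().ravel()
        np.testing.assert_allclose(filled[[2, 5]], coarse_vals[[2, 5]])
        np.testing.assert_allclose(filled[valid], series[valid])
        assert result.source.ravel()[2] == 2 and result.source.ravel()[5] == 2
        assert result.gap_stats["coarse_substituted_slots"] == 2

    def test_slot_mismatch_rejected(self):
        fine = slot_cube([0.1] * 8, harvest_year=2020)
        coarse = slot_cube([0.1] * 8, harvest_year=2021)
        with pytest.raises(ValueError):
            fuse(fine, coarse)
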