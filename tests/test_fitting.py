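"""Grid-search engine: amplitude optimization, R-squared, global optimum."""

import numpy as np
import pytest

from erlangfit import (
    AgeIncidenceSeries,
    Family,
    GridSpec,
    ParamPoint,
    SyntheticCohortConfig,
    area_estimate,
    compare_families,
    default_grid,
    fit_distribution,
    generate,
    golden_section_max,
    pdf,
    r_squared,
)
from erlangfit.errors import ConfigError, DegenerateDataError


def _series(rates, mids=None):
    rates = tuple(rates)
    mids = tuple(mids) if mids else tuple(float(i) + 0.5 for i in range(len(rates)))
    labels = tuple(f"bin{i}" for i in range(len(rates)))
    return AgeIncidenceSeries("test", labels, mids, rates)


class TestAreaEstimate:
    def test_plain_sum_of_rates(self):
        assert area_estimate(_series([1.0, 2.0, 3.0])) == 6.0

    def test_all_zero_rates_rejected(self):
        with pytest.raises(DegenerateDataError):
            area_estimate(_series([0.0, 0.0, 0.0]))


class TestGoldenSection:
    def test_interior_vertex(self):
        assert golden_section_max(lambda a: -((a - 3.0) ** 2), 0.0, 10.0, 1e-8) == (
            pytest.approx(3.0, abs=1e-6)
        )

    def test_maximizer_outside_bracket_clips_to_boundary(self):
        assert golden_section_max(lambda a: -((a - 3.0) ** 2), 5.0, 10.0, 1e-8) == (
            pytest.approx(5.0, abs=1e-6)
        )

    def test_invalid_bracket(self):
        with pytest.raises(ValueError):
            golden_section_max(lambda a: a, 2.0, 2.0)

    def test_deterministic(self):
        f = lambda a: -((a - 1.234) ** 2)
        assert golden_section_max(f, 0, 10) == golden_section_max(f, 0, 10)

    def test_matches_closed_form_amplitude(self, nephro_series):
        """Maximizing R-squared over A alone is least squares: A* = sum(yf)/sum(f^2)."""
        series, _ = nephro_series
        y = np.array(series.crude_rates)
        t = np.array(series.midpoints)
        area = area_estimate(series)
        for k, b in [(1.5, 2.0), (1.75, 2.2), (3.0, 1.0), (0.8, 4.0)]:
            f = np.asarray(pdf(Family.ERLANG_GAMMA, ParamPoint(k, b), t))
            obj = lambda a: -np.sum((y - a * f) ** 2)
            a_star = float(y @ f / (f @ f))
            assert area / 100 < a_star < area * 100
            a_gold = golden_section_max(obj, area / 100, area * 100, 1e-9)
            assert a_gold == pytest.approx(a_star, rel=1e-4)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert r_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        # SS_res = 1, SS_tot = 2
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitDistribution:
    def test_noiseless_roundtrip_recovers_truth(self, nephro_series, shape_grid_fine):
        series, truth = nephro_series
        fit = fit_distribution(series, Family.ERLANG_GAMMA, shape_grid_fine)
        assert fit.best_params == truth.true_params
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(truth.amplitude, rel=1e-4)

    def test_model_mismatch_scores_lower(self, nephro_series, shape_grid_fine):
        series, _ = nephro_series
        erlang = fit_distribution(series, Family.ERLANG_GAMMA, shape_grid_fine)
        weibull = fit_distribution(series, Family.WEIBULL, shape_grid_fine)
        assert weibull.r_squared < erlang.r_squared

    def test_landscape_consistency(self, nephro_series):
        series, _ = nephro_series
        grid = GridSpec.from_ranges(1.0, 3.0, 0.1, 1.0, 3.0, 0.1)
        fit = fit_distribution(series, Family.ERLANG_GAMMA, grid)
        assert fit.landscape.shape == grid.shape
        assert fit.r_squared == fit.landscape.max()
        assert fit.best_params.first in grid.first_param_values
        assert fit.best_params.second in grid.second_param_values
        area = area_estimate(series)
        assert area / 100 <= fit.amplitude <= area * 100

    def test_monotone_refinement(self, nephro_series):
        """Halving the grid step (a superset lattice) never lowers the best R2."""
        series, _ = nephro_series
        coarse = GridSpec.from_ranges(1.0, 3.0, 0.2, 1.0, 3.0, 0.2)
        fine = GridSpec.from_ranges(1.0, 3.0, 0.1, 1.0, 3.0, 0.1)
        assert set(coarse.first_param_values) <= set(fine.first_param_values)
        r_coarse = fit_distribution(series, Family.ERLANG_GAMMA, coarse).r_squared
        r_fine = fit_distribution(series, Family.ERLANG_GAMMA, fine).r_squared
        assert r_fine >= r_coarse - 1e-12

    def test_deterministic_repeat(self, nephro_series):
        series, _ = nephro_series
        grid = GridSpec.from_ranges(1.0, 2.5, 0.25, 1.5, 3.0, 0.25)
        a = fit_distribution(series, Family.ERLANG_GAMMA, grid)
        b = fit_distribution(series, Family.ERLANG_GAMMA, grid)
        assert a.best_params == b.best_params and a.amplitude == b.amplitude
        np.testing.assert_array_equal(a.landscape, b.landscape)

    def test_zero_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_distribution(_series([0.0, 0.0, 0.0]), Family.ERLANG_GAMMA)

    def test_shape_family_rejects_nonpositive_grid(self, nephro_series):
        series, _ = nephro_series
        bad = GridSpec.from_ranges(-1.0, 1.0, 0.5, 1.0, 2.0, 0.5)
        with pytest.raises(ConfigError):
            fit_distribution(series, Family.ERLANG_GAMMA, bad)

    def test_default_grid_dimensions(self):
        for family in Family:
            grid = default_grid(family)
            assert grid.shape == (400, 400)
            if family in (Family.ERLANG_GAMMA, Family.WEIBULL):
                assert grid.first_param_values[0] == pytest.approx(0.05)
            else:
                assert grid.first_param_values[0] == pytest.approx(-20.0)


class TestCompareFamilies:
    def test_erlang_generated_data_ranks_erlang_first(self, exponential_series):
        series, _ = exponential_series
        ranked = compare_families(series)
        assert ranked[0].family is Family.ERLANG_GAMMA
        flagged = {r.family for r in ranked if r.non_interpretable}
        assert {Family.NORMAL, Family.LOGISTIC} <= flagged
        assert Family.ERLANG_GAMMA not in flagged and Family.WEIBULL not in flagged

    def test_results_sorted_by_r_squared(self, nephro_series):
        series, _ = nephro_series
        ranked = compare_families(series)
        r2s = [r.fit.r_squared for r in ranked]
        assert all(a >= b - 1e-9 for a, b in zip(r2s, r2s[1:]))

    def test_single_family(self, nephro_series, shape_grid_fine):
        series, _ = nephro_series
        ranked = compare_families(
            series, [Family.ERLANG_GAMMA], grids={Family.ERLANG_GAMMA: shape_grid_fine}
        )
        assert len(ranked) == 1 and not ranked[0].non_interpretable

    def test_empty_family_list_rejected(self, nephro_series):
        series, _ = nephro_series
        with pytest.raises(ConfigError):
            compare_families(series, [])
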