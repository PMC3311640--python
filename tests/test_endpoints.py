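"""Dose-response, fecundity, lifespan and habituation statistics."""

import numpy as np
import pytest
from scipy.stats import norm

from wormscan.endpoints import (
    DoseGroup,
    SurvivalSeries,
    fecundity_curves,
    fit_probit,
    habituation_series,
    lc_p,
    lifespan_summary,
    simulate_dose_response,
)
from wormscan.segmentation import ThresholdSegmenter
from wormscan.synthetic_plates import SyntheticPlateSpec, render_time_series


def _grid_search_mle(groups, b0_range, b1_range, n=201):
    """Dense grid-search oracle for the probit MLE."""
    x = np.array([g.concentration for g in groups])
    nn = np.array([g.n_total for g in groups])
    d = np.array([g.n_dead for g in groups])
    b0s = np.linspace(*b0_range, n)
    b1s = np.linspace(*b1_range, n)
    best = (-np.inf, None, None)
    for b0 in b0s:
        mu = np.clip(norm.cdf(b0 + np.outer(b1s, x)), 1e-12, 1 - 1e-12)
        ll = (d * np.log(mu) + (nn - d) * np.log(1 - mu)).sum(axis=1)
        k = int(np.argmax(ll))
        if ll[k] > best[0]:
            best = (ll[k], b0, b1s[k])
    return best


class TestProbit:
    def test_symmetric_toy_puts_lc50_at_middle_dose(self):
        groups = [DoseGroup(100, 20, 2), DoseGroup(200, 20, 10), DoseGroup(300, 20, 18)]
        fit = fit_probit(groups)
        assert fit.converged
        assert fit.lc50 == pytest.approx(200.0, abs=1e-6)

    def test_flat_response_is_flagged_invalid(self):
        groups = [DoseGroup(c, 20, 10) for c in (100, 200, 300)]
        fit = fit_probit(groups)
        assert not fit.valid
        with pytest.raises(ValueError, match="converged fit"):
            lc_p(fit, 0.5)

    def test_matches_grid_search_oracle_to_three_sig_figs(self):
        rng = np.random.default_rng(5)
        doses = np.array([100, 150, 200, 250, 300, 350, 400], float)
        groups = simulate_dose_response(-3.37, 0.01, doses, 50, 3, rng)
        fit = fit_probit(groups)
        _ll, b0, b1 = _grid_search_mle(
            groups,
            (fit.intercept - 0.3, fit.intercept + 0.3),
            (fit.slope * 0.9, fit.slope * 1.1),
            n=601,
        )
        assert fit.intercept == pytest.approx(b0, rel=1e-3)
        assert fit.slope == pytest.approx(b1, rel=1e-3)
        oracle_lc50 = -b0 / b1
        assert fit.lc50 == pytest.approx(oracle_lc50, rel=1e-3)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        doses = np.array([50, 100, 200, 400, 800], float)
        groups = simulate_dose_response(-2.5, 0.012, doses, 40, 2, rng)
        fit = fit_probit(groups)
        x = np.array([g.concentration for g in groups])
        n = np.array([g.n_total for g in groups])
        d = np.array([g.n_dead for g in groups])
        res = sm.GLM(
            np.stack([d, n - d], axis=1),
            sm.add_constant(x),
            family=sm.families.Binomial(sm.families.links.Probit()),
        ).fit()
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-6)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-6)
        # our loglik is the binomial kernel; statsmodels adds ln C(n, d)
        from scipy.special import gammaln

        binom_const = np.sum(gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1))
        assert fit.loglik + binom_const == pytest.approx(res.llf, rel=1e-9)

    def test_parameter_recovery_from_simulated_assay(self):
        # 7 doses x 50 worms x 3 replicates around a known LC50
        rng = np.random.default_rng(12)
        true_b0, true_b1 = -3.37, 0.01  # LC50 = 337 ppm
        doses = np.linspace(100, 650, 7)
        biases = []
        for _ in range(5):
            groups = simulate_dose_response(true_b0, true_b1, doses, 50, 3, rng)
            fit = fit_probit(groups)
            biases.append(fit.lc50 / 337.0 - 1)
        assert max(abs(b) for b in biases) < 0.05

    def test_complete_separation_warns_and_penalizes(self):
        groups = [DoseGroup(100, 20, 0), DoseGroup(300, 20, 20)]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_probit(groups)
        assert fit.penalized
        assert np.isfinite(fit.lc50)

    def test_log10_dose_scale_back_transforms(self):
        rng = np.random.default_rng(3)
        doses = np.array([10, 50, 100, 500, 1000, 5000], float)
        groups = simulate_dose_response(-7.0, 3.0, doses, 60, 3, rng, dose_scale="log10")
        fit = fit_probit(groups, dose_scale="log10")
        assert fit.lc50 == pytest.approx(10 ** (7.0 / 3.0), rel=0.15)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n_dead"):
            DoseGroup(10, 5, 7)
        with pytest.raises(ValueError, match="distinct"):
            fit_probit([DoseGroup(10, 5, 1), DoseGroup(10, 5, 2)])
        with pytest.raises(ValueError, match="all-alive"):
            fit_probit([DoseGroup(10, 5, 0), DoseGroup(20, 5, 0)])


class TestLcP:
    @pytest.fixture()
    def fit(self):
        groups = [DoseGroup(100, 40, 4), DoseGroup(200, 40, 20), DoseGroup(300, 40, 36)]
        return fit_probit(groups)

    def test_p_half_is_minus_b0_over_b1(self, fit):
        assert lc_p(fit, 0.5) == pytest.approx(-fit.intercept / fit.slope)

    def test_strictly_monotone_in_p(self, fit):
        ps = np.linspace(0.05, 0.95, 19)
        doses = [lc_p(fit, p) for p in ps]
        assert all(b > a for a, b in zip(doses, doses[1:]))

    def test_round_trip_through_predicted_mortality(self, fit):
        dose = lc_p(fit, 0.25)
        assert fit.predict(dose) == pytest.approx(0.25, abs=1e-9)

    def test_p_out_of_range_rejected(self, fit):
        with pytest.raises(ValueError):
            lc_p(fit, 1.0)


class TestFecundity:
    def test_cumulative_is_running_sum(self):
        series = fecundity_curves(np.array([[0, 10, 20, 5]]))
        assert series.cumulative_mean.tolist() == [0, 10, 30, 35]

    def test_all_zero_counts_give_zero_series(self):
        series = fecundity_curves(np.zeros((3, 5)))
        assert not series.cumulative_mean.any()
        assert not series.per_day_ci.any()

    def test_ragged_day_grids_rejected(self):
        with pytest.raises(ValueError, match="ragged|inhomogeneous"):
            fecundity_curves([[1, 2, 3], [1, 2]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fecundity_curves(np.array([[1, -2]]))

    def test_interval_covers_true_mean_at_nominal_rate(self):
        # with ~30 replicates the normal approximation is adequate
        rng = np.random.default_rng(8)
        true_mean = np.array([5.0, 40.0, 60.0, 30.0, 10.0])
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            counts = rng.poisson(true_mean, size=(30, 5))
            s = fecundity_curves(counts)
            hits += np.all((s.per_day_ci[0] <= true_mean) & (true_mean <= s.per_day_ci[1]))
        # joint coverage of 5 pointwise-95% bands is lower than 95%
        assert 0.70 <= hits / n_sim <= 0.99


class TestLifespan:
    def test_mean_of_death_days(self):
        summ = lifespan_summary([np.array([10.0, 20.0])])
        assert summ.mean_days == 15.0
        assert summ.n_deaths == 2

    def test_deaths_inferred_from_decreasing_counts(self):
        series = SurvivalSeries(days=np.arange(5), n_alive=[[48, 48, 40, 30, 30]])
        days = series.death_days()[0]
        assert len(days) == 18
        assert sorted(set(days.tolist())) == [2, 3]

    def test_increasing_counts_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SurvivalSeries(days=np.arange(3), n_alive=[[10, 12, 9]])

    def test_no_deaths_rejected(self):
        with pytest.raises(ValueError, match="no deaths"):
            lifespan_summary([np.array([])])

    def test_recovers_simulated_mean_lifespan(self):
        # 3 trials x 48 worms with death days ~ Normal(17.3, 4)
        rng = np.random.default_rng(17)
        trials = [rng.normal(17.3, 4.0, size=48) for _ in range(3)]
        summ = lifespan_summary(trials)
        assert abs(summ.mean_days - 17.3) <= 3 * (4.0 / np.sqrt(3 * 48))
        assert np.isfinite(summ.se_days)
        assert len(summ.trial_means) == 3


class TestHabituation:
    def test_twenty_one_scans_give_twenty_intervals(self):
        n_worms, n_scans = 6, 21
        # startle response decays over intervals, then extinguishes;
        # values keep clear of the 0.10 response threshold
        schedule = np.r_[np.linspace(0.7, 0.25, 6), np.zeros(14)]
        per_int = np.tile(schedule[:, None], (1, n_worms))
        spec = SyntheticPlateSpec(
            width_px=900, height_px=900, n_worms=n_worms,
            worm_length_mm_range=(0.5, 1.0), noise_sd=0.005, seed=83,
        )
        scans, _truth = render_time_series(spec, n_scans=n_scans, per_scan_displacements=per_int)
        series = habituation_series(scans, ThresholdSegmenter(), min_area_px=150)
        assert len(series.responding_fraction) == 20
        assert np.all(np.diff(series.responding_fraction) <= 1e-12)
        assert series.responding_fraction[0] == 1.0
        assert series.responding_fraction[-1] == 0.0

    def test_all_moving_every_interval_scores_one(self):
        n_worms = 5
        per_int = np.full((2, n_worms), 0.5)
        spec = SyntheticPlateSpec(
            width_px=700, height_px=700, n_worms=n_worms, noise_sd=0.005, seed=89,
        )
        scans, _ = render_time_series(spec, n_scans=3, per_scan_displacements=per_int)
        series = habituation_series(scans, ThresholdSegmenter())
        assert series.responding_fraction.tolist() == [1.0, 1.0]

    def test_fewer_than_two_scans_rejected(self):
        with pytest.raises(ValueError, match="two scans"):
            habituation_series([None], ThresholdSegmenter())
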