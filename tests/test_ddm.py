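"""Drift-diffusion engine: drift mapping, first-passage solvers, simulator,
likelihood and trimming. (Heavy grid cross-checks and fitting recovery live in
the acceptance suite.)"""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from choicedyn.ddm import (
    Condition,
    DDMParams,
    choice_prob_closed_form,
    drift_from_condition,
    fpt_solve,
    simulate_ddm,
    trial_likelihood,
    trim_to_percentile,
)

COND = Condition(8, 2)


class TestDrift:
    def test_log_contrast(self):
        assert drift_from_condition(1.0, COND) == pytest.approx(math.log(4))

    def test_equal_luminance_is_zero(self):
        assert drift_from_condition(2.0, Condition(5, 5)) == 0.0

    def test_contrast_invariance(self):
        assert drift_from_condition(1.3, Condition(16, 4)) == pytest.approx(
            drift_from_condition(1.3, COND)
        )

    def test_rejects_nonpositive_luminance(self):
        with pytest.raises(ValueError):
            Condition(0, 2)


class TestChoiceProb:
    def test_symmetric_no_drift(self):
        p = DDMParams(drift_coef=0.0, boundary_sep=2.0, nondecision_t=0.0,
                      start_offset=0.0)
        assert choice_prob_closed_form(p, COND) == pytest.approx(0.5)

    def test_zero_drift_biased_start_is_z_over_a(self):
        p = DDMParams(drift_coef=0.0, boundary_sep=2.0, nondecision_t=0.0,
                      start_offset=0.1)
        assert choice_prob_closed_form(p, COND) == pytest.approx(1.1 / 2.0)

    def test_scale_invariance_of_choice_probability(self):
        """Scaling (k, a, z0, s) by a common factor leaves P unchanged —
        the degeneracy that motivates fixing the noise parameter."""
        p1 = DDMParams(drift_coef=1.5, boundary_sep=2.0, nondecision_t=0.3)
        c = 2.7  # rescale the evidence axis: x -> c x scales v, a, z0, s alike
        p2 = DDMParams(drift_coef=1.5 * c, boundary_sep=2.0 * c, nondecision_t=0.3,
                       noise=p1.noise * c, start_offset=p1.start_offset * c)
        assert choice_prob_closed_form(p1, COND) == pytest.approx(
            choice_prob_closed_form(p2, COND), rel=1e-12
        )

    def test_invalid_start_offset(self):
        with pytest.raises(ValueError):
            DDMParams(drift_coef=1.0, boundary_sep=0.15, nondecision_t=0.0)


class TestFirstPassage:
    P = DDMParams(drift_coef=1.5, boundary_sep=2.0, nondecision_t=0.3)

    def test_series_conserves_probability(self):
        sol = fpt_solve(self.P, COND, dt=0.005, T=8.0, method="series")
        assert sol.p_high + sol.p_low + sol.p_undecided == pytest.approx(1.0, abs=1e-4)
        assert (sol.dens_high >= 0).all() and (sol.dens_low >= 0).all()

    def test_series_matches_closed_form_choice_prob(self):
        sol = fpt_solve(self.P, COND, dt=0.002, T=10.0, method="series")
        pc = choice_prob_closed_form(self.P, COND)
        assert sol.p_high == pytest.approx(pc, abs=1e-4)

    def test_pde_matches_series(self):
        s1 = fpt_solve(self.P, COND, dt=0.001, T=6.0, method="series")
        s2 = fpt_solve(self.P, COND, dt=0.001, T=6.0, method="pde", nx=800)
        assert np.max(np.abs(s1.dens_high - s2.dens_high)) < 1e-3
        assert np.max(np.abs(s1.dens_low - s2.dens_low)) < 1e-3
        assert s2.p_high == pytest.approx(choice_prob_closed_form(self.P, COND),
                                          abs=1e-3)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            fpt_solve(self.P, COND, dt=0.05, T=6.0)
        with pytest.raises(ValueError):
            fpt_solve(self.P, COND, dt=0.005, T=1.0)


class TestTrialLikelihood:
    P = DDMParams(drift_coef=1.5, boundary_sep=2.0, nondecision_t=0.3)

    def test_sub_nondecision_latency_floored_without_lapse(self):
        import dataclasses

        p = dataclasses.replace(self.P, lapse_mix=0.0)
        sol = fpt_solve(p, COND)
        val = trial_likelihood(p, COND, "high", 0.1, sol)
        assert val == pytest.approx(1e-12)

    def test_pure_lapse_limit(self):
        import dataclasses

        p = dataclasses.replace(self.P, lapse_mix=0.999999)
        sol = fpt_solve(p, COND)
        lat = 0.8
        expected = p.lapse_mix * 0.5 * p.lapse_rate * math.exp(-p.lapse_rate * lat)
        assert trial_likelihood(p, COND, "low", lat, sol) == pytest.approx(
            expected, rel=1e-4
        )

    def test_normalizes_over_choices_and_time(self):
        sol = fpt_solve(self.P, COND, dt=0.002, T=12.0)
        t = np.arange(0, 12.0, 0.002)
        total = sum(
            np.trapezoid(trial_likelihood(self.P, COND, c, t, sol), t)
            for c in ("high", "low")
        )
        assert total == pytest.approx(1.0, abs=1e-3)


class TestSimulator:
    P = DDMParams(drift_coef=1.5, boundary_sep=2.0, nondecision_t=0.3)

    def test_deterministic_under_seed(self):
        a = simulate_ddm(self.P, COND, 500, seed=3)
        b = simulate_ddm(self.P, COND, 500, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_choice_fraction_matches_mixed_closed_form(self):
        n = 60_000
        ch, _ = simulate_ddm(self.P, COND, n, dt=0.002, seed=12)
        pc = choice_prob_closed_form(self.P, COND)
        p_obs = (1 - self.P.lapse_mix) * pc + self.P.lapse_mix / 2
        se = math.sqrt(p_obs * (1 - p_obs) / n)
        assert abs(np.mean(ch == "high") - p_obs) < 3 * se

    def test_latency_distribution_matches_density(self):
        """KS distance between simulated latencies and the lapse-mixed model CDF."""
        n = 60_000
        ch, lat = simulate_ddm(self.P, COND, n, dt=0.001, seed=13)
        sol = fpt_solve(self.P, COND, dt=0.002, T=25.0)
        t = sol.time_grid
        dens = sum(
            trial_likelihood(self.P, COND, c, t, sol) for c in ("high", "low")
        )
        cdf = np.cumsum(dens) * 0.002
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(lat), t, side="right") / n
        assert np.max(np.abs(emp - cdf)) < 0.012


class TestTrim:
    def test_keeps_95_of_100_distinct(self):
        x = np.arange(100, dtype=float)
        kept, cut = trim_to_percentile(x, 95)
        assert len(kept) == 95  # linear-interpolation percentile of 0..99 is 94.05
        assert cut == pytest.approx(np.percentile(x, 95))

    def test_degenerate_all_equal(self):
        kept, _ = trim_to_percentile(np.full(50, 0.5), 95)
        assert len(kept) == 50

    def test_retained_fraction_on_exgauss_draws(self):
        from choicedyn.exgauss import ExGaussParams, exgauss_sample

        x = exgauss_sample(ExGaussParams(0.45, 0.05, 0.15), 10_000, seed=2)
        kept, _ = trim_to_percentile(x, 95)
        frac = len(kept) / len(x)
        assert abs(frac - 0.95) < 3 * math.sqrt(0.95 * 0.05 / len(x)) + 1e-3

    def test_percentile_bounds(self):
        with pytest.raises(ValueError):
            trim_to_percentile(np.arange(10.0), 40)
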