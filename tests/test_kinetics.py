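import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nimotif.kinetics import (
    ConsecutiveKinetics,
    FitError,
    HillCurve,
    KineticTimeCourse,
    consecutive_model,
    first_order_model,
    fit_consecutive,
    fit_first_order,
    fit_hill,
    hill_model,
    intermediate_peak_time,
    rate_ratio,
    sum_site_rates,
    t_half,
)
from nimotif.simulate import gen_timecourse, gen_titration


def ode_oracle(t, k1, k2, A0):
    """Numerical integration of A -> B -> C as an independent check."""
    def rhs(_, y):
        A, B, C = y
        return [-k1 * A, k1 * A - k2 * B, k2 * B]

    sol = solve_ivp(
        rhs, (0, float(np.max(t))), [A0, 0.0, 0.0],
        t_eval=np.atleast_1d(t), rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return sol.y


class TestConsecutiveModel:
    def test_initial_condition(self):
        A, B, C = consecutive_model(0.0, 0.1, 0.05, 0.8)
        assert (A, B, C) == (pytest.approx(0.8), pytest.approx(0.0), pytest.approx(0.0))

    def test_completion(self):
        A, B, C = consecutive_model(1e6, 0.1, 0.05, 0.8)
        assert A == pytest.approx(0.0, abs=1e-12)
        assert C == pytest.approx(0.8, abs=1e-9)

    def test_reference_point(self):
        A, B, C = consecutive_model(10.0, 0.2, 0.1, 1.0)
        assert A == pytest.approx(0.13534, abs=1e-4)
        assert B == pytest.approx(0.46508, abs=1e-4)
        assert C == pytest.approx(0.39958, abs=1e-4)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            consecutive_model(1.0, 0.0, 0.1)

    @pytest.mark.parametrize("k1", [0.001, 0.01, 0.1, 1.0])
    @pytest.mark.parametrize("k2", [0.001, 0.031623, 1.0])
    def test_mass_conservation_over_three_decades(self, k1, k2):
        t = np.linspace(0, 5000, 200)
        A, B, C = consecutive_model(t, k1, k2, 0.9)
        assert np.max(np.abs(A + B + C - 0.9)) < 1e-10

    def test_mass_conservation_degenerate_branch(self):
        t = np.linspace(0, 100, 50)
        A, B, C = consecutive_model(t, 0.05, 0.05 * (1 + 1e-12), 1.0)
        assert np.max(np.abs(A + B + C - 1.0)) < 1e-10

    @pytest.mark.parametrize("k1,k2", [(0.001, 0.1), (0.05, 0.05001), (1.0, 0.002)])
    def test_agrees_with_numerical_ode(self, k1, k2):
        t = np.linspace(0.1, 3.0 / min(k1, k2), 40)
        A, B, C = consecutive_model(t, k1, k2, 1.0)
        Ao, Bo, Co = ode_oracle(t, k1, k2, 1.0)
        assert np.max(np.abs(A - Ao)) < 1e-6
        assert np.max(np.abs(B - Bo)) < 1e-6
        assert np.max(np.abs(C - Co)) < 1e-6

    def test_intermediate_maximum_at_analytic_time(self):
        k1, k2 = 0.2, 0.05
        tstar = intermediate_peak_time(k1, k2)
        assert tstar == pytest.approx(np.log(k1 / k2) / (k1 - k2))
        eps = 1e-5
        B = lambda t: consecutive_model(t, k1, k2, 1.0)[1]
        assert B(tstar) >= B(tstar - eps) and B(tstar) >= B(tstar + eps)


class TestFitConsecutive:
    def test_noiseless_recovery_is_exact(self):
        tc, _ = gen_timecourse(0.1, 0.05, 1.0, sigma=0.0, seed=0)
        fit = fit_consecutive(tc)
        assert fit.k1_ == pytest.approx(0.1, rel=1e-6)
        assert fit.k2_ == pytest.approx(0.05, rel=1e-6)
        assert fit.A0_ == pytest.approx(1.0, rel=1e-6)

    def test_noisy_recovery_single_seed(self):
        tc, _ = gen_timecourse(0.1, 0.05, 1.0, sigma=0.01, seed=42)
        fit = fit_consecutive(tc, n_starts=3)
        assert fit.k1_ == pytest.approx(0.1, rel=0.05)
        assert fit.k2_ == pytest.approx(0.05, rel=0.05)

    def test_swapped_rate_basin_has_no_lower_residual(self):
        tc, _ = gen_timecourse(0.05, 0.1, 1.0, sigma=0.005, seed=7)
        fit = fit_consecutive(tc)
        # refit constrained near the swapped ordering and compare residuals
        est = ConsecutiveKinetics(n_starts=1, rate_grid=(0.1, 0.1))
        Y = np.column_stack([tc.fractions[s] for s in ("substrate", "intermediate", "product")])
        est.fit(tc.times, Y)
        assert fit.residual_ <= est.residual_ + 1e-12

    def test_band_contains_fitted_curve(self):
        tc, _ = gen_timecourse(0.1, 0.05, 1.0, sigma=0.01, seed=3)
        fit = fit_consecutive(tc)
        grid = np.linspace(0, tc.times.max(), 30)
        lo, hi = fit.confidence_band(grid, species="substrate")
        curve = fit.predict(grid)[:, 0]
        assert np.all(lo <= curve + 1e-12) and np.all(curve <= hi + 1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            ConsecutiveKinetics().fit([0, 1, 2], np.zeros((3, 3)))

    def test_sequential_mode_matches_joint_closely(self):
        tc, _ = gen_timecourse(0.1, 0.05, 1.0, sigma=0.0, seed=0)
        fit = fit_consecutive(tc, mode="sequential")
        assert fit.k1_ == pytest.approx(0.1, rel=1e-4)


class TestTimeCourseContainer:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            KineticTimeCourse(np.array([0.0, 0.0, 1.0]), {"substrate": np.zeros(3)})

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            KineticTimeCourse(np.array([0.0, 1.0]), {"substrate": np.array([0.0, 1.2])})

    def test_from_long_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_min": [0, 0, 10, 10],
                "species": ["substrate", "product"] * 2,
                "fraction": [1.0, 0.0, 0.5, 0.4],
                "condition": ["harsh"] * 4,
            }
        )
        tc = KineticTimeCourse.from_frame(df, condition="harsh")
        assert list(tc.times) == [0, 10]
        assert tc.fractions["product"][1] == 0.4


class TestFirstOrder:
    def test_half_life_arithmetic(self):
        t = np.linspace(0, 120, 10)
        y = first_order_model(t, 0.0347, 1.0)
        fit = fit_first_order(t, y)
        assert fit.t_half_ == pytest.approx(np.log(2) / 0.0347, rel=1e-6)
        assert fit.t_half_ == pytest.approx(20.0, rel=0.01)

    def test_flat_zero_signal_is_error(self):
        with pytest.raises(FitError, match="no signal"):
            fit_first_order(np.arange(6.0), np.zeros(6))

    def test_noisy_recovery(self):
        rngs = np.random.default_rng(11)
        t = np.linspace(0, 150, 12)
        y = first_order_model(t, 0.03, 0.95) + rngs.normal(0, 0.01, t.size)
        fit = fit_first_order(t, y)
        assert fit.k_ == pytest.approx(0.03, rel=0.05)


class TestRateArithmetic:
    def test_sum_and_ratio(self):
        out = sum_site_rates([0.01, 0.02, 0.03], observed_domain_rate=0.30)
        assert out["sum"] == pytest.approx(0.06)
        assert out["observed_over_sum"] == pytest.approx(5.0)

    def test_empty_sum(self):
        assert sum_site_rates([])["sum"] == 0.0

    def test_identical_fits_ratio_one(self):
        r, se = rate_ratio(0.1, 0.1, 0.0, 0.0)
        assert r == 1.0 and se == 0.0

    def test_tenfold_ratio(self):
        r, _ = rate_ratio(0.5, 0.05)
        assert r == pytest.approx(10.0)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            rate_ratio(0.1, 0.0)

    def test_simulated_condition_pair_within_fifteen_percent(self):
        harsh, _ = gen_timecourse(0.2, 0.1, 1.0, sigma=0.01, seed=21)
        phys, _ = gen_timecourse(0.02, 0.01, 1.0, sigma=0.01, seed=22)
        fh = fit_consecutive(harsh, n_starts=3)
        fp = fit_consecutive(phys, n_starts=3)
        r, _ = rate_ratio(fh, fp)
        assert r == pytest.approx(10.0, rel=0.15)


class TestHill:
    def test_midpoint_symmetry(self):
        assert hill_model(5.6, 5.6, 2.0, 0.2, 0.8) == pytest.approx(0.5)

    def test_plateaus(self):
        assert hill_model(13.0, 5.6, 1.0, 0.0, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert hill_model(0.0, 5.6, 1.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_reference_point(self):
        assert hill_model(6.6, 5.6, 1.0, 0.0, 1.0) == pytest.approx(10 / 11)

    def test_noiseless_fit_exact(self):
        tab, _ = gen_titration(5.6, 1.3, 0.05, 0.9, sigma=0.0)
        fit = fit_hill(tab)
        assert fit.pKa_ == pytest.approx(5.6, abs=1e-6)
        assert fit.n_hill_ == pytest.approx(1.3, abs=1e-5)

    def test_noisy_recovery_within_tenth_of_unit(self):
        tab, _ = gen_titration(5.6, 1.0, 0.0, 1.0, sigma=0.02, seed=8)
        fit = fit_hill(tab)
        assert abs(fit.pKa_ - 5.6) < 0.1

    def test_decreasing_titration_pka_unchanged(self):
        up, _ = gen_titration(5.6, 1.0, 0.0, 1.0, sigma=0.0)
        down, _ = gen_titration(5.6, 1.0, 1.0, 0.0, sigma=0.0)
        assert fit_hill(up).pKa_ == pytest.approx(fit_hill(down).pKa_, abs=1e-6)
        assert fit_hill(down).A_max_ < fit_hill(down).A_min_

    def test_no_transition_is_error(self):
        import pandas as pd

        flat = pd.DataFrame({"pH": np.linspace(3, 11, 10), "signal": np.ones(10)})
        with pytest.raises(FitError):
            fit_hill(flat)
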