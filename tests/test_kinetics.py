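"""Exponential-sum fitting, AICc selection and TIAC integration."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from prrtdose import (
    LU177,
    BloodModelParams,
    ExpSumModel,
    FitError,
    NoiseModel,
    apply_systematic_error,
    fit_exp_sum,
    select_model,
    simulate_blood_tac,
    tac_from_arrays,
    tiac_analytic,
    tiac_trapezoid_tail,
)
from prrtdose.kinetics import TIACResult
from prrtdose.synthetic import STUDY_SCHEDULE

LAM_P = LU177.decay_constant
EARLY_BLOOD_H = np.array([0.5, 1, 2, 5, 10, 20, 30, 50, 75, 100, 200, 300]) / 60.0


class TestFitExpSum:
    def test_noiseless_monoexponential_exact(self):
        lam = math.log(2) / 0.6  # 36 min half-time
        t = np.linspace(0.05, 3.0, 10)
        fit = fit_exp_sum((t, np.exp(-lam * t)), 1, n_starts=5)
        assert fit.model.rates_per_h[0] == pytest.approx(lam, rel=1e-6)
        assert fit.weighted_ssr < 1e-12

    def test_noiseless_biexponential_blood_defaults(self):
        tac = simulate_blood_tac(BloodModelParams(), EARLY_BLOOD_H)
        fit = fit_exp_sum(tac, 2, n_starts=8)
        half_lives_min = [h * 60 for h in fit.model.half_lives_h]
        assert half_lives_min[0] == pytest.approx(2.0, rel=1e-4)
        assert half_lives_min[1] == pytest.approx(36.0, rel=1e-4)
        amps = fit.model.amplitudes
        assert amps[0] / sum(amps) == pytest.approx(0.801, rel=1e-4)

    def test_insufficient_points_names_minimum(self):
        with pytest.raises(FitError, match="5 points"):
            fit_exp_sum(([1.0, 2.0, 3.0], [1.0, 0.5, 0.2]), 2)

    def test_requires_decay_corrected_tac(self):
        tac = tac_from_arrays("s", "liver", [1, 2, 3], [0.3, 0.2, 0.1], decay_corrected=False)
        with pytest.raises(ValueError, match="decay-corrected"):
            fit_exp_sum(tac, 1)

    def test_canonical_order_fastest_first(self):
        tac = simulate_blood_tac(BloodModelParams(), EARLY_BLOOD_H)
        fit = fit_exp_sum(tac, 2, n_starts=8)
        assert fit.model.rates_per_h[0] > fit.model.rates_per_h[1]

    def test_reproducible_given_seed(self, rng):
        tac = simulate_blood_tac(BloodModelParams(), EARLY_BLOOD_H, NoiseModel(0.05), rng)
        a = fit_exp_sum(tac, 2, seed=3)
        b = fit_exp_sum(tac, 2, seed=3)
        assert a.model == b.model

    def test_mean_recovered_beta_half_life_small_sample(self, rng):
        # cheap version of the Monte-Carlo recovery contract (full run in acceptance)
        betas = []
        for i in range(50):
            tac = simulate_blood_tac(BloodModelParams(), EARLY_BLOOD_H, NoiseModel(0.05), rng)
            fit = fit_exp_sum(tac, 2, n_starts=4, seed=i)
            betas.append(fit.model.half_lives_h[1] * 60)
        assert np.mean(betas) == pytest.approx(36.0, rel=0.10)


class TestSelectModel:
    def test_parsimony_on_monoexponential_data(self):
        lam = math.log(2) / 5.0
        t = np.linspace(0.1, 30.0, 25)
        y = 0.5 * np.exp(-lam * t) * (1 + 1e-6 * np.sin(t))  # break exact degeneracy
        fit = select_model((t, y), (1, 2, 3), n_starts=5)
        assert fit.model.n_terms == 1

    def test_two_separated_terms_on_study_schedule(self):
        tac = simulate_blood_tac(BloodModelParams(), EARLY_BLOOD_H, NoiseModel(0.02))
        fit = select_model(tac, (1, 2), n_starts=6)
        assert fit.model.n_terms == 2
        # brute-force AICc comparison across the candidates
        f1 = fit_exp_sum(tac, 1, n_starts=6)
        f2 = fit_exp_sum(tac, 2, n_starts=6)
        assert f2.aicc < f1.aicc

    def test_three_points_admit_only_one_term(self):
        fit = select_model(([1.0, 2.0, 4.0], [0.4, 0.25, 0.1]), (1, 2, 3), n_starts=4)
        assert fit.model.n_terms == 1

    def test_no_fittable_candidate_fails_loudly(self):
        with pytest.raises(FitError):
            select_model(([1.0, 2.0], [0.4, 0.2]), (2, 3))


class TestTiacAnalytic:
    def test_physical_decay_only_bound(self):
        from prrtdose.kinetics import FitResult

        model = ExpSumModel((1.0,), (0.0,))
        fit = FitResult(model, np.zeros((2, 2)), 0.0, 0.0, 10, "1/y2")
        tiac = tiac_analytic(fit, LU177)
        assert tiac.value_h == pytest.approx(159.528 / math.log(2), rel=1e-9)
        assert tiac.value_h == pytest.approx(230.15, abs=0.005)

    def test_closed_form_rate_equal_physical(self):
        from prrtdose.kinetics import FitResult

        model = ExpSumModel((0.5,), (LAM_P,))
        fit = FitResult(model, np.zeros((2, 2)), 0.0, 0.0, 10, "1/y2")
        assert tiac_analytic(fit, LU177).value_h == pytest.approx(0.25 / LAM_P, rel=1e-12)

    def test_matches_adaptive_quadrature_on_blood_fit(self):
        # blood defaults expressed as fraction of IA held in a 2-litre pool
        params = BloodModelParams()
        times = np.geomspace(0.01, 10.0, 40)
        pool_fraction = params.concentration(times * 60.0) / 100.0 * 2.0
        fit = fit_exp_sum((times, pool_fraction), 2, n_starts=6)
        tiac = tiac_analytic(fit, LU177)
        oracle, err = integrate.quad(
            lambda t: fit.model.predict(t) * math.exp(-LAM_P * t), 0, np.inf, limit=200
        )
        assert tiac.value_h == pytest.approx(oracle, rel=1e-8)

    def test_uncertainty_matches_parametric_bootstrap(self, rng):
        """Propagated TIAC SE vs a 2000-draw parametric bootstrap oracle."""
        params = BloodModelParams()
        tac = simulate_blood_tac(params, EARLY_BLOOD_H, NoiseModel(0.05), rng)
        fit = fit_exp_sum(tac, 2, n_starts=6, seed=1)
        se = tiac_analytic(fit, LU177).standard_error_h
        s = math.sqrt(fit.weighted_ssr / (fit.n_points - fit.n_params))
        t = EARLY_BLOOD_H
        yhat = np.asarray(fit.model.predict(t))
        p_hat = np.array(
            [v for pair in zip(fit.model.amplitudes, fit.model.rates_per_h) for v in pair]
        )
        n_terms = fit.model.n_terms

        def resid_factory(y):
            w = 1.0 / y

            def resid(p):
                amps, rates = p[0::2], p[1::2]
                return w * (np.exp(-np.outer(t, rates)) @ amps - y)

            return resid

        draws = []
        for _ in range(2000):
            y_star = yhat * (1.0 + s * rng.standard_normal(t.size))
            sol = optimize.least_squares(
                resid_factory(y_star), p_hat, bounds=(0.0, np.inf), method="trf"
            )
            amps, rates = sol.x[0::2], sol.x[1::2]
            draws.append(np.sum(amps / (rates + LAM_P)))
        assert np.std(draws, ddof=1) == pytest.approx(se, rel=0.15)


class TestSystematicError:
    def test_pure_systematic(self):
        tiac = TIACResult("liver", 10.0, 0.0, "analytic")
        assert apply_systematic_error(tiac).standard_error_h == pytest.approx(1.0)

    def test_quadrature_addition(self):
        tiac = TIACResult("liver", 10.0, 1.0, "analytic")
        assert apply_systematic_error(tiac).standard_error_h == pytest.approx(math.sqrt(2.0))

    def test_zero_value_unchanged(self):
        tiac = TIACResult("liver", 0.0, 0.3, "analytic")
        assert apply_systematic_error(tiac).standard_error_h == pytest.approx(0.3)

    def test_double_application_rejected(self):
        tiac = apply_systematic_error(TIACResult("liver", 10.0, 0.0, "analytic"))
        with pytest.raises(ValueError, match="already"):
            apply_systematic_error(tiac)


class TestTrapezoidTail:
    def test_dense_physical_decay_matches_analytic(self):
        t = np.linspace(1e-4, 10 * 159.528, 1000)
        values = np.exp(-LAM_P * t)
        tac = tac_from_arrays("s", "bladder_contents", t, values, decay_corrected=False)
        tiac = tiac_trapezoid_tail(tac, LU177)
        assert tiac.value_h == pytest.approx(1.0 / LAM_P, rel=1e-3)

    def test_all_zero_samples(self):
        tac = tac_from_arrays("s", "bladder_contents", [1.0, 2.0], [0.0, 0.0], decay_corrected=False)
        assert tiac_trapezoid_tail(tac, LU177).value_h == 0.0

    def test_tail_term_for_constant_corrected_series(self):
        tac = tac_from_arrays("s", "bladder_contents", [1.0, 2.0, 4.0], [0.01] * 3)
        tiac = tiac_trapezoid_tail(tac, LU177)
        expected_tail = 0.01 * math.exp(-LAM_P * 4.0) / LAM_P
        # subtract the triangle+trapezoid area over [0, 4] computed by hand
        f = lambda t: 0.01 * math.exp(-LAM_P * t)
        area = 0.5 * 1.0 * f(1) + 0.5 * (f(1) + f(2)) + 0.5 * 2 * (f(2) + f(4))
        assert tiac.value_h - area == pytest.approx(expected_tail, rel=1e-12)

    def test_single_sample_rejected(self):
        tac = tac_from_arrays("s", "bladder_contents", [1.0], [0.1], decay_corrected=False)
        with pytest.raises(FitError):
            tiac_trapezoid_tail(tac, LU177)

    def test_agrees_with_analytic_on_dense_exponential(self):
        lam_bio = math.log(2) / 50.0
        t = np.linspace(0.01, 2000, 4000)
        corrected = 0.3 * np.exp(-lam_bio * t)
        tac = tac_from_arrays("s", "bladder_contents", t, corrected)
        trap = tiac_trapezoid_tail(tac, LU177).value_h
        analytic = 0.3 / (lam_bio + LAM_P)
        assert trap == pytest.approx(analytic, rel=0.01)


class TestBounds:
    def test_tiac_never_exceeds_physical_decay_bound(self):
        # any fitted organ TIAC <= peak fraction / lambda_phys
        from prrtdose.synthetic import DEFAULT_ORGAN_PARAMS, simulate_organ_tac

        for params in DEFAULT_ORGAN_PARAMS.values():
            tac = simulate_organ_tac(params, LU177, STUDY_SCHEDULE.imaging_times_h)
            fit = select_model(tac, (1, 2, 3), n_starts=4)
            tiac = tiac_analytic(fit, LU177)
            assert tiac.value_h <= max(tac.values) / LAM_P + 1e-9
            assert tiac.value_h <= 230.16
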