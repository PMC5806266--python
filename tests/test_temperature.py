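"""Temperature rate laws, joint elementary-rate fit, optima, thermostability."""

import numpy as np
import pandas as pd
import pytest

from enzkin import (
    ElementaryRates,
    InactivationArrheniusModel,
    ResidualActivityTable,
    fit_inactivation_model,
    fit_temperature_profiles,
    predict_temperature_model,
    simulate_temperature_profile,
    simulate_thermostability,
    temperature_optimum,
    thermostability_summary,
)
from enzkin.exceptions import (
    EmptyInputError,
    InvalidParameterError,
    InvalidSelectorError,
)
from conftest import make_spec


class TestRateLaws:
    def test_eq3_at_t0_equal_rates(self):
        r = ElementaryRates(k1_0=1.0, km1_0=1.0, k2_0=1.0, k3_0=1.0,
                            e1=5e4, em1=5e4, e2=5e4, e3=5e4)
        assert predict_temperature_model(r, "eq3", 313.15) == pytest.approx(0.5)

    def test_eq2b_forced_arithmetic_at_t0(self):
        r = ElementaryRates(k1_0=2.0, km1_0=1.0, k2_0=1.0, k3_0=1.0,
                            e1=1e4, em1=1e4, e2=1e4, e3=1e4)
        assert predict_temperature_model(r, "eq2b", 313.15) == pytest.approx(1.0)

    def test_eq2b_binding_limited(self):
        """With k2 >> k-1 the efficiency collapses to k1(T)."""
        r = ElementaryRates(k1_0=3.0, km1_0=1e-6, k2_0=1.0, k3_0=1.0,
                            e1=4e4, em1=4e4, e2=4e4, e3=4e4)
        for t in (293.15, 313.15, 333.15):
            assert predict_temperature_model(r, "eq2b", t) == pytest.approx(
                float(r.k1(t)), rel=1e-5)

    def test_eq2a_at_t0(self):
        m = InactivationArrheniusModel(alpha0=3.0, e_alpha=2e5, k1_0=2.0, e1=5e4)
        assert predict_temperature_model(m, "eq2a", 313.15) == pytest.approx(
            (3.0 / 4.0) * 2.0, rel=1e-12)

    def test_selector_mismatch(self):
        m = InactivationArrheniusModel(alpha0=1.0, e_alpha=2e5, k1_0=2.0, e1=5e4)
        with pytest.raises(InvalidSelectorError):
            predict_temperature_model(m, "eq2b", 313.15)

    def test_bounds_hold_on_random_models(self):
        """eq2b <= k1(T) and eq3 <= min(k2, k3) on 1000 random models."""
        rng = np.random.default_rng(123)
        t = np.linspace(283.15, 353.15, 15)
        for _ in range(1000):
            r = ElementaryRates(
                k1_0=rng.lognormal(0, 2), km1_0=rng.lognormal(-3, 2),
                k2_0=rng.lognormal(-3, 2), k3_0=rng.lognormal(-3, 2),
                e1=rng.uniform(0, 2e5), em1=rng.uniform(0, 2e5),
                e2=rng.uniform(0, 2e5), e3=rng.uniform(0, 2e5))
            assert (r.predict_kcat_km(t) <= r.k1(t) * (1 + 1e-12)).all()
            assert (r.predict_kcat(t)
                    <= np.minimum(r.k2(t), r.k3(t)) * (1 + 1e-12)).all()


class TestJointFit:
    def test_noiseless_self_consistency(self, reference_rates):
        grid = tuple(range(20, 76, 5))
        pkm = simulate_temperature_profile(reference_rates, "kcatKm_2b",
                                           make_spec(3, grid))
        pk = simulate_temperature_profile(reference_rates, "kcat_3",
                                          make_spec(3, grid))
        fit = fit_temperature_profiles(pkm, pk)
        t = np.array(grid) + 273.15
        np.testing.assert_allclose(fit.rates.predict_kcat_km(t),
                                   reference_rates.predict_kcat_km(t),
                                   rtol=1e-8)
        np.testing.assert_allclose(fit.rates.predict_kcat(t),
                                   reference_rates.predict_kcat(t), rtol=1e-8)

    def test_refit_on_own_predictions_is_stable(self, reference_rates):
        grid = tuple(range(20, 76, 5))
        pkm = simulate_temperature_profile(reference_rates, "kcatKm_2b",
                                           make_spec(1, grid))
        pk = simulate_temperature_profile(reference_rates, "kcat_3",
                                          make_spec(1, grid))
        fit = fit_temperature_profiles(pkm, pk)
        t = np.array(grid) + 273.15
        pkm2 = simulate_temperature_profile(fit.rates, "kcatKm_2b",
                                            make_spec(1, grid))
        pk2 = simulate_temperature_profile(fit.rates, "kcat_3",
                                           make_spec(1, grid))
        fit2 = fit_temperature_profiles(pkm2, pk2)
        np.testing.assert_allclose(fit2.rates.predict_kcat_km(t),
                                   fit.rates.predict_kcat_km(t), rtol=1e-10)
        np.testing.assert_allclose(fit2.rates.predict_kcat(t),
                                   fit.rates.predict_kcat(t), rtol=1e-10)

    def test_constrained_fit_recovers_all_parameters(self, reference_rates):
        """Pinning the reverse step (k-1 at T0 and its energy) breaks the
        ratio and swap degeneracies: every parameter recovers."""
        grid = tuple(range(20, 76, 5))
        pkm = simulate_temperature_profile(reference_rates, "kcatKm_2b",
                                           make_spec(2, grid))
        pk = simulate_temperature_profile(reference_rates, "kcat_3",
                                          make_spec(2, grid))
        fit = fit_temperature_profiles(
            pkm, pk, {"fixed": {"km1_0": reference_rates.km1_0,
                                "em1": reference_rates.em1}})
        for name in ("k1_0", "k2_0", "k3_0", "e1", "e2", "e3"):
            assert getattr(fit.rates, name) == pytest.approx(
                getattr(reference_rates, name), rel=1e-4), name

    def test_flat_profiles_flagged(self):
        grid = tuple(range(20, 76, 5))
        flat = ElementaryRates(k1_0=2.0, km1_0=1.0, k2_0=1.0, k3_0=1.0,
                               e1=0.0, em1=0.0, e2=0.0, e3=0.0)
        pkm = simulate_temperature_profile(flat, "kcatKm_2b", make_spec(0, grid))
        pk = simulate_temperature_profile(flat, "kcat_3", make_spec(0, grid))
        with pytest.warns(UserWarning, match="temperature-independent"):
            fit = fit_temperature_profiles(pkm, pk)
        assert any("temperature-independent" in w for w in fit.warnings)

    def test_identifiability_report_present(self, reference_rates):
        grid = tuple(range(20, 76, 5))
        pkm = simulate_temperature_profile(reference_rates, "kcatKm_2b",
                                           make_spec(4, grid, noise=0.03))
        pk = simulate_temperature_profile(reference_rates, "kcat_3",
                                          make_spec(5, grid, noise=0.03))
        fit = fit_temperature_profiles(pkm, pk)
        assert fit.identifiability["condition_number"] > 0
        assert "free_parameters" in fit.identifiability


class TestInactivationFit:
    def test_noiseless_round_trip(self):
        truth = InactivationArrheniusModel(alpha0=1.0, e_alpha=2.0e5,
                                           k1_0=2.0, e1=5.0e4)
        grid = tuple(range(20, 76, 5))
        prof = simulate_temperature_profile(truth, "kcatKm_2a", make_spec(0, grid))
        est = fit_inactivation_model(prof)
        for name in ("alpha0", "e_alpha", "k1_0", "e1"):
            assert getattr(est.model_, name) == pytest.approx(
                getattr(truth, name), rel=1e-5), name
        assert not est.non_identified_

    def test_noisy_optimum_within_one_degree(self):
        truth = InactivationArrheniusModel(alpha0=1.0, e_alpha=2.0e5,
                                           k1_0=2.0, e1=5.0e4)
        true_opt = temperature_optimum(truth, "eq2a", (283.15, 353.15))
        grid = tuple(range(20, 76, 4))
        opts = []
        for seed in range(20):
            prof = simulate_temperature_profile(truth, "kcatKm_2a",
                                                make_spec(seed, grid,
                                                          noise=0.03, reps=4))
            est = fit_inactivation_model(prof)
            opts.append(temperature_optimum(est.model_, "eq2a",
                                            (283.15, 353.15)).temperature_K)
        assert np.mean(np.abs(np.array(opts) - true_opt.temperature_K)) < 1.0

    def test_monotone_profile_flagged(self):
        # pure Arrhenius data (no inactivation): monotone, non-identified
        truth = InactivationArrheniusModel(alpha0=1e6, e_alpha=1e4,
                                           k1_0=2.0, e1=5.0e4)
        grid = tuple(range(20, 76, 5))
        prof = simulate_temperature_profile(truth, "kcatKm_2a", make_spec(0, grid))
        with pytest.warns(UserWarning):
            est = fit_inactivation_model(prof)
        assert est.non_identified_


class TestOptimum:
    def test_matches_dense_grid_search(self, reference_rates):
        res = temperature_optimum(reference_rates, "eq2b", (283.15, 353.15))
        grid = np.arange(283.15, 353.15, 0.01)
        vals = predict_temperature_model(reference_rates, "eq2b", grid)
        assert abs(res.temperature_K - grid[np.argmax(vals)]) <= 0.02
        assert not res.at_boundary

    def test_monotone_curve_boundary_flag(self, reference_rates):
        # eq3 with positive energies is monotone increasing in T
        res = temperature_optimum(reference_rates, "eq3", (283.15, 343.15))
        assert res.temperature_K == pytest.approx(343.15)
        assert res.at_boundary

    def test_scale_invariance(self, reference_rates):
        import dataclasses

        scaled = dataclasses.replace(reference_rates,
                                     k1_0=reference_rates.k1_0 * 37.0)
        a = temperature_optimum(reference_rates, "eq2b", (283.15, 353.15))
        b = temperature_optimum(scaled, "eq2b", (283.15, 353.15))
        assert a.temperature_K == pytest.approx(b.temperature_K, abs=1e-6)

    def test_kcat_optimum_above_kcatkm_optimum(self, reference_rates):
        """With E3 >> E2 the kcat profile culminates at higher temperature
        than the kcat/Km profile of the shared-parameter model."""
        lo, hi = 283.15, 353.15
        a = temperature_optimum(reference_rates, "eq2b", (lo, hi))
        b = temperature_optimum(reference_rates, "eq3", (lo, hi))
        assert b.temperature_K > a.temperature_K


class TestThermostability:
    def test_stable_enzyme_reports_top_of_grid(self):
        table = simulate_thermostability(80.0, 0.35,
                                         make_spec(0, tuple(range(20, 71, 5))))
        assert thermostability_summary(table, 0.95) == 70.0

    def test_all_below_threshold_reports_none(self):
        table = simulate_thermostability(10.0, 0.5,
                                         make_spec(0, tuple(range(20, 71, 5))))
        assert thermostability_summary(table, 0.95) is None

    def test_threshold_contract(self):
        table = simulate_thermostability(80.0, 0.35, make_spec(0, (20.0, 30.0)))
        with pytest.raises(InvalidParameterError):
            thermostability_summary(table, 0.0)
        with pytest.raises(InvalidParameterError):
            thermostability_summary(table, 1.5)

    def test_empty_table_rejected(self):
        table = ResidualActivityTable(
            pd.DataFrame(columns=["preincubation_temp_C", "residual_activity"]))
        with pytest.raises(EmptyInputError):
            thermostability_summary(table, 0.95)
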