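"""Michaelis-Menten fitting: exact recovery, oracle agreement, invariances."""

import numpy as np
import pytest
from scipy.stats import binomtest

from enzkin import (
    MichaelisMentenParams,
    MichaelisMentenRegressor,
    compare_salt_effect,
    estimate_from_regimes,
    fit_michaelis_menten,
    simulate_velocity_curve,
)
from enzkin.exceptions import (
    InvalidComparisonError,
    InvalidDesignError,
)
from conftest import make_spec


def grid_search_oracle(s, v, n=200):
    """Brute-force least squares over a log grid in (Vmax, Km)."""
    vmax_grid = np.exp(np.linspace(np.log(v.max() * 0.5), np.log(v.max() * 4), n))
    km_grid = np.exp(np.linspace(np.log(s[s > 0].min() / 4),
                                 np.log(s.max() * 4), n))
    best = (np.inf, None, None)
    for vm in vmax_grid:
        pred = vm * s[None, :] / (km_grid[:, None] + s[None, :])
        sse = ((pred - v[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (sse[i], vm, km_grid[i])
    return best[1], best[2]


class TestFullFit:
    def test_noiseless_recovery_of_published_values(self, acetate_mm,
                                                    substrate_grid):
        data = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(0, substrate_grid))
        fit = fit_michaelis_menten(data)
        assert fit.kcat == pytest.approx(1.736e-3, rel=1e-8)
        assert fit.km_mM == pytest.approx(0.473, rel=1e-8)
        assert fit.kcat_over_km == pytest.approx(3.671, abs=1e-3)

    def test_half_saturation_definition(self):
        """Data where v([S]=Km) = Vmax/2 exactly pins Km to that [S]."""
        s = np.array([0.1, 0.25, 0.8, 2.0, 8.0, 40.0])
        vmax, km = 2.0e-9, 0.8
        v = vmax * s / (km + s)
        est = MichaelisMentenRegressor(enzyme_conc_nM=850.0)
        est.fit(s.reshape(-1, 1), v)
        assert est.km_ == pytest.approx(km, rel=1e-9)

    def test_agrees_with_grid_search_oracle(self, acetate_mm, substrate_grid):
        data = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(42, substrate_grid,
                                                 noise=0.03, reps=8))
        fit = fit_michaelis_menten(data)
        f = data.frame
        s, v = f["substrate_conc_mM"].to_numpy(), f["velocity"].to_numpy()
        vm_o, km_o = grid_search_oracle(s, v)
        # refine the oracle once around its optimum for a fair comparison
        vm_o2, km_o2 = grid_search_oracle(
            s, v, n=400)
        assert fit.km_mM == pytest.approx(km_o2, rel=2e-2)
        e_molar = 850e-9
        assert fit.kcat == pytest.approx(vm_o2 / e_molar, rel=2e-2)

    def test_row_order_and_rescaling_invariance(self, acetate_mm,
                                                substrate_grid):
        data = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(5, substrate_grid,
                                                 noise=0.02, reps=4))
        f = data.frame
        est = MichaelisMentenRegressor(enzyme_conc_nM=850.0)
        X = f[["substrate_conc_mM"]].to_numpy()
        y = f["velocity"].to_numpy()
        a = est.fit(X, y).params_
        perm = np.random.default_rng(0).permutation(len(y))
        b = MichaelisMentenRegressor(enzyme_conc_nM=850.0).fit(
            X[perm], y[perm]).params_
        assert a.kcat == pytest.approx(b.kcat, rel=1e-9)
        # doubling velocities and [E] together leaves kcat and Km unchanged
        c = MichaelisMentenRegressor(enzyme_conc_nM=1700.0).fit(X, 2 * y).params_
        assert c.kcat == pytest.approx(a.kcat, rel=1e-9)
        assert c.km_mM == pytest.approx(a.km_mM, rel=1e-9)

    def test_recovery_study_unbiased(self, acetate_mm, substrate_grid):
        """100 seeded 3%-noise datasets: median relative error < 5% and no
        systematic sign bias in the Km estimates (sign test p > 0.01)."""
        km_err, kcat_err = [], []
        for seed in range(100):
            data = simulate_velocity_curve(
                acetate_mm, 850.0,
                make_spec(seed, substrate_grid, noise=0.03, reps=8))
            fit = fit_michaelis_menten(data)
            km_err.append(fit.km_mM / 0.473 - 1.0)
            kcat_err.append(fit.kcat / 1.736e-3 - 1.0)
        assert np.median(np.abs(km_err)) < 0.05
        assert np.median(np.abs(kcat_err)) < 0.05
        n_pos = int(np.sum(np.array(km_err) > 0))
        assert binomtest(n_pos, 100).pvalue > 0.01

    def test_needs_four_distinct_concentrations(self):
        s = np.array([0.5, 0.5, 1.0, 2.0])
        v = s / (1 + s) * 1e-9
        with pytest.raises(InvalidDesignError):
            MichaelisMentenRegressor(enzyme_conc_nM=850.0).fit(
                s.reshape(-1, 1), v)

    def test_saturation_warning_flag(self):
        s = np.array([0.01, 0.02, 0.04, 0.08, 0.15])
        km, vmax = 5.0, 1e-9
        v = vmax * s / (km + s)
        with pytest.warns(UserWarning, match="saturation"):
            est = MichaelisMentenRegressor(enzyme_conc_nM=850.0).fit(
                s.reshape(-1, 1), v)
        assert est.saturation_warning_

    def test_kcat_over_km_always_consistent(self):
        p = MichaelisMentenParams("x", kcat=0.040, km_mM=1.926)
        assert p.kcat_over_km == pytest.approx(p.kcat / (p.km_mM * 1e-3),
                                               rel=1e-12)


class TestTwoRegimeProtocol:
    def test_low_regime_slope_exact(self, acetate_mm):
        low = simulate_velocity_curve(acetate_mm, 850.0,
                                      make_spec(0, (0.001, 0.002, 0.004, 0.008)))
        high = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(0, (23.65,)))  # 50 x Km
        est = estimate_from_regimes(low, high)
        # low-[S] limit: v/[S][E] -> kcat/Km, small upward [S]/Km correction
        assert est.kcat_over_km == pytest.approx(acetate_mm.kcat_over_km,
                                                 rel=2e-2)

    def test_high_regime_plateau_bias_below_2pct(self, acetate_mm):
        high = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(0, (23.65,)))
        low = simulate_velocity_curve(acetate_mm, 850.0,
                                      make_spec(0, (0.001, 0.002)))
        est = estimate_from_regimes(low, high)
        # closed form: plateau underestimates kcat by Km/(Km+[S]) ~ 1.96%
        assert est.kcat == pytest.approx(acetate_mm.kcat, rel=2e-2)
        assert est.kcat < acetate_mm.kcat

    def test_two_regime_agrees_with_full_fit(self, acetate_mm, substrate_grid):
        full = fit_michaelis_menten(simulate_velocity_curve(
            acetate_mm, 850.0, make_spec(9, substrate_grid, noise=0.02, reps=8)))
        low = simulate_velocity_curve(acetate_mm, 850.0,
                                      make_spec(10, (0.002, 0.005, 0.01),
                                                noise=0.02, reps=8))
        high = simulate_velocity_curve(acetate_mm, 850.0,
                                       make_spec(11, (20.0, 30.0),
                                                 noise=0.02, reps=8))
        two = estimate_from_regimes(low, high)
        assert two.kcat == pytest.approx(full.kcat, rel=0.05)
        assert two.kcat_over_km == pytest.approx(full.kcat_over_km, rel=0.05)

    def test_regime_overlap_rejected(self, acetate_mm):
        low = simulate_velocity_curve(acetate_mm, 850.0, make_spec(0, (0.1, 5.0)))
        high = simulate_velocity_curve(acetate_mm, 850.0, make_spec(0, (2.0,)))
        with pytest.raises(InvalidDesignError):
            estimate_from_regimes(low, high)


class TestSaltEffect:
    def test_identity_gives_100_percent(self):
        p = MichaelisMentenParams("ac", kcat=1.736e-3, km_mM=0.473)
        rep = compare_salt_effect(p, p, "NaCl", 10.0)
        for ratio in (rep.ratio_kcat, rep.ratio_Km, rep.ratio_kcatKm):
            assert ratio == pytest.approx(100.0, rel=1e-12)

    def test_halved_kcat_pattern(self):
        """kcat halved at unchanged Km: the NaCl-like signature."""
        c = MichaelisMentenParams("ac", kcat=1.736e-3, km_mM=0.473)
        t = MichaelisMentenParams("ac", kcat=0.868e-3, km_mM=0.473)
        rep = compare_salt_effect(c, t, "NaCl", 10.0)
        assert rep.ratio_kcat == pytest.approx(50.0)
        assert rep.ratio_Km == pytest.approx(100.0)
        assert rep.ratio_kcatKm == pytest.approx(50.0)

    def test_raised_km_pattern(self):
        """Km x1.5 alone: the divalent-salt signature (Km ~150%)."""
        c = MichaelisMentenParams("ac", kcat=1.736e-3, km_mM=0.473)
        t = MichaelisMentenParams("ac", kcat=1.736e-3, km_mM=0.473 * 1.5)
        rep = compare_salt_effect(c, t, "CaCl2", 10.0)
        assert rep.ratio_Km == pytest.approx(150.0)
        assert rep.ratio_kcatKm == pytest.approx(100 / 1.5, abs=0.05)

    def test_substrate_mismatch_rejected(self):
        a = MichaelisMentenParams("ac", kcat=1.0, km_mM=1.0)
        b = MichaelisMentenParams("bu", kcat=1.0, km_mM=1.0)
        with pytest.raises(InvalidComparisonError):
            compare_salt_effect(a, b, "NaCl", 10.0)
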