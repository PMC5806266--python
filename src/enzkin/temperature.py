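"""Temperature dependence of kcat/Km and kcat for a serine-hydrolase scheme.

Mechanistic background.  The minimal acyl-enzyme scheme

    E + S  <-k1/k-1->  ES  --k2-->  E_acyl  --k3-->  E + P

gives kcat/Km = k1.k2/(k-1 + k2) and kcat = k2.k3/(k2 + k3).  Each elementary
constant is given an Arrhenius temperature dependence relative to a reference
temperature T0,

    k_i(T) = (k_i)_0 . exp[-E_i/R . (1/T - 1/T0)],

so that the two observable profiles become (with the numerator energy E1+E2
for kcat/Km and E2+E3 for kcat):

    kcat/Km(T) = (k1)_0 (k2)_0 e^{-(E1+E2)/R (1/T-1/T0)}
                 / [ (k-1)_0 e^{-E-1/R (1/T-1/T0)} + (k2)_0 e^{-E2/R (1/T-1/T0)} ]
    kcat(T)    = (k2)_0 (k3)_0 e^{-(E2+E3)/R (1/T-1/T0)}
                 / [ (k2)_0 e^{-E2/R (1/T-1/T0)} + (k3)_0 e^{-E3/R (1/T-1/T0)} ]

An alternative descriptive model couples a reversible-inactivation sigmoid to
a single Arrhenius rise (:class:`InactivationArrheniusModel`), producing the
familiar rise-then-fall activity optimum.

Identifiability.  From the kcat/Km equation alone only k1 and the ratio
k-1/k2 are identified (kcat/Km = k1/(1 + k-1/k2)); sharing (k2_0, E2) with
the kcat equation partially resolves this, and the joint fit reports a
covariance-based identifiability diagnosis plus support for user-fixed
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .constants import R
from .datasets import ProfileDataset, ResidualActivityTable
from .exceptions import (
    EmptyInputError,
    FitError,
    InvalidDesignError,
    InvalidParameterError,
    InvalidSelectorError,
)


def _arrhenius(k0, e, t, t0):
    """k(T) = k0 exp(-E/R (1/T - 1/T0))."""
    t = np.asarray(t, dtype=float)
    return k0 * np.exp(-e / R * (1.0 / t - 1.0 / t0))


@dataclass(frozen=True)
class ElementaryRates:
    """Elementary rate constants at T0 and their activation energies.

    k1_0 in M^-1 s^-1 (bimolecular association); km1_0, k2_0, k3_0 in s^-1.
    Energies in J mol^-1.  T0 in K (defaults to the 40 degC assay).
    """

    k1_0: float
    km1_0: float
    k2_0: float
    k3_0: float
    e1: float
    em1: float
    e2: float
    e3: float
    t0: float = 313.15

    def __post_init__(self):
        for name in ("k1_0", "km1_0", "k2_0", "k3_0"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("e1", "em1", "e2", "e3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    def k1(self, t):
        return _arrhenius(self.k1_0, self.e1, t, self.t0)

    def km1(self, t):
        return _arrhenius(self.km1_0, self.em1, t, self.t0)

    def k2(self, t):
        return _arrhenius(self.k2_0, self.e2, t, self.t0)

    def k3(self, t):
        return _arrhenius(self.k3_0, self.e3, t, self.t0)

    def predict_kcat_km(self, t):
        """kcat/Km(T) = k1 k2 / (k-1 + k2); never exceeds k1(T)."""
        return self.k1(t) * self.k2(t) / (self.km1(t) + self.k2(t))

    def predict_kcat(self, t):
        """kcat(T) = k2 k3 / (k2 + k3); never exceeds min(k2, k3)."""
        return self.k2(t) * self.k3(t) / (self.k2(t) + self.k3(t))


@dataclass(frozen=True)
class InactivationArrheniusModel:
    """Reversible-inactivation sigmoid times an Arrhenius rise.

    kcat/Km(T) = [a(T)/(1+a(T))] . k1_0 e^{-E1/R (1/T-1/T0)}  with
    a(T) = alpha0 e^{+E_alpha/R (1/T-1/T0)}: the active fraction decays at
    high temperature while the intrinsic rate rises, producing an optimum.
    """

    alpha0: float
    e_alpha: float
    k1_0: float
    e1: float
    t0: float = 313.15

    def __post_init__(self):
        if not (self.alpha0 > 0 and self.k1_0 > 0):
            raise InvalidParameterError("alpha0 and k1_0 must be positive")
        if self.e_alpha < 0 or self.e1 < 0:
            raise InvalidParameterError("energies must be non-negative")

    def active_fraction(self, t):
        a = _arrhenius(self.alpha0, -self.e_alpha, t, self.t0)
        return a / (1.0 + a)

    def predict(self, t):
        return self.active_fraction(t) * _arrhenius(self.k1_0, self.e1, t, self.t0)


def predict_temperature_model(model, which: str, t):
    """Evaluate one of the temperature rate laws at T (K).

    ``which`` selects the equation: 'eq2a' (inactivation x Arrhenius, needs
    an InactivationArrheniusModel), 'eq2b' (kcat/Km from elementary rates)
    or 'eq3' (kcat from elementary rates).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise InvalidParameterError("absolute temperature must be positive")
    if which == "eq2a":
        if not isinstance(model, InactivationArrheniusModel):
            raise InvalidSelectorError("eq2a requires an InactivationArrheniusModel")
        return model.predict(t)
    if which == "eq2b":
        if not isinstance(model, ElementaryRates):
            raise InvalidSelectorError("eq2b requires ElementaryRates")
        return model.predict_kcat_km(t)
    if which == "eq3":
        if not isinstance(model, ElementaryRates):
            raise InvalidSelectorError("eq3 requires ElementaryRates")
        return model.predict_kcat(t)
    raise InvalidSelectorError(f"unknown selector {which!r}")


_PARAM_NAMES = ("k1_0", "km1_0", "k2_0", "k3_0", "e1", "em1", "e2", "e3")
_LOG_PARAMS = frozenset(("k1_0", "km1_0", "k2_0", "k3_0"))


@dataclass(frozen=True)
class ElementaryRatesFit:
    """Joint-fit result: rates, errors, and identifiability diagnosis."""

    rates: ElementaryRates
    se: dict
    identifiability: dict
    warnings: tuple = ()
    rss: float = float("nan")


class ElementaryRatesRegressor(RegressorMixin, BaseEstimator):
    """Joint nonlinear least squares of the kcat/Km and kcat rate laws.

    Design matrix ``X`` has two columns: absolute temperature (K) and a
    profile indicator (0 -> kcat/Km observation, 1 -> kcat observation);
    ``y`` holds the observed parameter values.  (k2_0, E2) are shared
    between the two equations.  Residuals are scaled by each profile's
    maximum so the two (very differently scaled) observables contribute
    comparably.

    Parameters
    ----------
    t0 : reference temperature, K.
    fixed : optional dict {param name: value} pinning parameters
        (names: k1_0, km1_0, k2_0, k3_0, e1, em1, e2, e3).
    n_starts : multistart count for the seeded global search.
    random_state : seed for the start draws.
    """

    def __init__(self, t0=313.15, fixed=None, n_starts=16, random_state=0):
        self.t0 = t0
        self.fixed = fixed
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=6)
        t = X[:, 0]
        ind = X[:, 1].astype(int)
        if not set(np.unique(ind)) <= {0, 1}:
            raise InvalidSelectorError("profile indicator must be 0 or 1")
        if np.any(t <= 0):
            raise InvalidParameterError("temperatures must be in K and positive")
        m_km, m_k = ind == 0, ind == 1
        if m_km.sum() < 3 or m_k.sum() < 3:
            raise InvalidDesignError("both profiles need >= 3 observations")
        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(_PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown fixed parameter(s): {sorted(unknown)}")

        scale_km = float(np.max(np.abs(y[m_km])))
        scale_k = float(np.max(np.abs(y[m_k])))
        if scale_km <= 0 or scale_k <= 0:
            raise FitError("profiles contain no positive observations")
        w = np.where(m_km, 1.0 / scale_km, 1.0 / scale_k)

        free = [p for p in _PARAM_NAMES if p not in fixed]

        def unpack(theta):
            values = dict(fixed)
            with np.errstate(over="ignore"):
                for name, val in zip(free, theta):
                    if name in _LOG_PARAMS:
                        # floor against exp underflow in degenerate corners
                        values[name] = max(float(np.exp(val)), 1e-300)
                    else:
                        values[name] = float(val)
            return values

        def residuals(theta):
            v = unpack(theta)
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                du_km = 1 / t[m_km] - 1 / self.t0
                du_k = 1 / t[m_k] - 1 / self.t0
                km_pred = (v["k1_0"] * v["k2_0"]
                           * np.exp(-(v["e1"] + v["e2"]) / R * du_km)
                           / (v["km1_0"] * np.exp(-v["em1"] / R * du_km)
                              + v["k2_0"] * np.exp(-v["e2"] / R * du_km)))
                k_pred = (v["k2_0"] * v["k3_0"]
                          * np.exp(-(v["e2"] + v["e3"]) / R * du_k)
                          / (v["k2_0"] * np.exp(-v["e2"] / R * du_k)
                             + v["k3_0"] * np.exp(-v["e3"] / R * du_k)))
                out = np.empty_like(y)
                out[m_km] = km_pred
                out[m_k] = k_pred
                res = (out - y) * w
            return np.nan_to_num(res, nan=1e6, posinf=1e6, neginf=-1e6)

        starts = self._starts(y[m_km], y[m_k], free)
        lb = np.array([-np.inf if p in _LOG_PARAMS else 0.0 for p in free])
        ub = np.full(len(free), np.inf)
        best = None
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for x0 in starts:
                try:
                    sol = least_squares(residuals, x0=x0, bounds=(lb, ub),
                                        method="trf", xtol=1e-15, ftol=1e-15,
                                        gtol=1e-15, max_nfev=4000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitError("joint temperature fit failed from every start")
        sol = best

        values = unpack(sol.x)
        rates = ElementaryRates(t0=self.t0, **values)
        se = self._standard_errors(sol, free, values)
        ident = self._identifiability(sol, free)
        warns = []
        pred_km = rates.predict_kcat_km(t[m_km])
        pred_k = rates.predict_kcat(t[m_k])
        flat = all(np.ptp(p) / np.max(p) < 1e-3 for p in (pred_km, pred_k))
        if flat:
            warns.append("temperature-independent profiles: all effective "
                         "activation energies ~ 0")
            warnings.warn(warns[-1])
        if ident["condition_number"] > 1e8:
            warns.append("parameter covariance is ill-conditioned; see "
                         "identifiability report")

        self.rates_ = rates
        self.fit_ = ElementaryRatesFit(rates=rates, se=se, identifiability=ident,
                                       warnings=tuple(warns),
                                       rss=float(2.0 * sol.cost))
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "rates_")
        X = check_array(X)
        t, ind = X[:, 0], X[:, 1].astype(int)
        out = np.where(ind == 0, self.rates_.predict_kcat_km(t),
                       self.rates_.predict_kcat(t))
        return out

    # -- helpers -----------------------------------------------------------
    def _starts(self, y_km, y_k, free):
        rng = np.random.default_rng(self.random_state)
        base = {
            "k1_0": 2.0 * float(np.max(y_km)),
            "km1_0": 2.0 * float(np.max(y_k)),
            "k2_0": 2.0 * float(np.max(y_k)),
            "k3_0": 2.0 * float(np.max(y_k)),
            "e1": 5e4, "em1": 5e4, "e2": 5e4, "e3": 8e4,
        }
        starts = []
        for i in range(max(int(self.n_starts), 1)):
            x0 = []
            for p in free:
                v = base[p]
                if p in _LOG_PARAMS:
                    jitter = 1.0 if i == 0 else float(np.exp(rng.normal(0, 1.5)))
                    x0.append(np.log(v * jitter))
                else:
                    jitter = 1.0 if i == 0 else float(rng.uniform(0.2, 3.0))
                    x0.append(v * jitter)
            starts.append(np.array(x0))
        return starts

    @staticmethod
    def _standard_errors(sol, free, values):
        from .mm import _asymptotic_se

        se_internal = _asymptotic_se(sol)
        se = {}
        for name, s in zip(free, se_internal):
            se[name] = values[name] * s if name in _LOG_PARAMS else s
        return se

    @staticmethod
    def _identifiability(sol, free):
        jac = sol.jac
        u, sv, vt = np.linalg.svd(jac, full_matrices=False)
        sv = np.where(sv <= 0, np.finfo(float).tiny, sv)
        cond = float(sv[0] / sv[-1])
        flagged = []
        for i, s in enumerate(sv):
            if s < 1e-6 * sv[0]:
                weights = vt[i]
                names = [free[j] for j in np.argsort(-np.abs(weights))[:3]]
                flagged.append({"singular_value": float(s), "parameters": names})
        return {"condition_number": cond, "flagged_directions": flagged,
                "free_parameters": list(free)}


def fit_temperature_profiles(kcatKm_profile: ProfileDataset,
                             kcat_profile: ProfileDataset,
                             config: Optional[dict] = None) -> ElementaryRatesFit:
    """Joint fit of both observable profiles; see ElementaryRatesRegressor.

    Both profiles must be measured at the same assay pH and carry >= 6
    temperatures each.  ``config`` may supply ``t0``, ``fixed``, ``n_starts``,
    ``random_state``.
    """
    cfg = dict(config or {})
    if (kcatKm_profile.pH is not None and kcat_profile.pH is not None
            and kcatKm_profile.pH != kcat_profile.pH):
        raise InvalidDesignError(
            f"profiles measured at different pH: {kcatKm_profile.pH} vs "
            f"{kcat_profile.pH}"
        )
    for prof, label in ((kcatKm_profile, "kcat/Km"), (kcat_profile, "kcat")):
        if prof.frame["x_name"].iloc[0] != "temperature_C":
            raise InvalidDesignError(f"{label} profile is not a temperature profile")
        if prof.frame["x"].nunique() < 6:
            raise InvalidDesignError(f"{label} profile needs >= 6 temperatures")
    t_km = kcatKm_profile.x + 273.15
    t_k = kcat_profile.x + 273.15
    X = np.column_stack([
        np.concatenate([t_km, t_k]),
        np.concatenate([np.zeros(len(t_km)), np.ones(len(t_k))]),
    ])
    y = np.concatenate([kcatKm_profile.values, kcat_profile.values])
    est = ElementaryRatesRegressor(
        t0=cfg.get("t0", 313.15), fixed=cfg.get("fixed"),
        n_starts=cfg.get("n_starts", 16),
        random_state=cfg.get("random_state", 0),
    )
    est.fit(X, y)
    return est.fit_


class InactivationArrheniusRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the inactivation x Arrhenius model to a
    kcat/Km-vs-T profile.  X is temperature in K (one column), y the rate."""

    def __init__(self, t0=313.15, n_starts=16, random_state=0):
        self.t0 = t0
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=5)
        t = X[:, 0]
        if np.any(t <= 0):
            raise InvalidParameterError("temperatures must be in K and positive")
        order = np.argsort(t)
        imax = int(np.argmax(y[order]))
        monotone = imax in (0, len(y) - 1)
        if monotone:
            warnings.warn("profile maximum at grid boundary: inactivation "
                          "parameters not identified from a monotone profile")
        scale = float(np.max(np.abs(y)))

        def residuals(theta):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                alpha0 = np.exp(theta[0])
                e_alpha = theta[1]
                k1_0 = np.exp(theta[2])
                e1 = theta[3]
                a = alpha0 * np.exp(e_alpha / R * (1 / t - 1 / self.t0))
                frac = np.where(np.isfinite(a), a / (1 + a), 1.0)
                pred = frac * k1_0 * np.exp(-e1 / R * (1 / t - 1 / self.t0))
                res = (pred - y) / scale
            return np.nan_to_num(res, nan=1e6, posinf=1e6, neginf=-1e6)

        rng = np.random.default_rng(self.random_state)
        lb = np.array([-np.inf, 0.0, -np.inf, 0.0])
        ub = np.array([np.inf, np.inf, np.inf, np.inf])
        best = None
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for i in range(max(int(self.n_starts), 1)):
                if i == 0:
                    x0 = np.array([0.0, 1.5e5, np.log(2.0 * scale), 5e4])
                else:
                    x0 = np.array([rng.normal(0, 2), rng.uniform(2e4, 4e5),
                                   np.log(scale * np.exp(rng.normal(0.7, 1.0))),
                                   rng.uniform(1e4, 1.5e5)])
                try:
                    sol = least_squares(residuals, x0=x0, bounds=(lb, ub),
                                        method="trf", xtol=1e-15, ftol=1e-15,
                                        gtol=1e-15, max_nfev=4000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitError("inactivation-model fit failed from every start")
        sol = best
        self.model_ = InactivationArrheniusModel(
            alpha0=float(np.exp(sol.x[0])), e_alpha=float(sol.x[1]),
            k1_0=float(np.exp(sol.x[2])), e1=float(sol.x[3]), t0=self.t0,
        )
        self.non_identified_ = bool(monotone or self.model_.e_alpha < 1e3)
        if self.model_.e_alpha < 1e3 and not monotone:
            warnings.warn("fitted E_alpha ~ 0: model collapsed to a pure "
                          "Arrhenius curve times a constant")
        self.rss_ = float(2.0 * sol.cost * scale**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.predict(X[:, 0])


def fit_inactivation_model(kcatKm_profile: ProfileDataset,
                           config: Optional[dict] = None):
    """Fit the inactivation x Arrhenius model to a temperature profile."""
    cfg = dict(config or {})
    if kcatKm_profile.frame["x_name"].iloc[0] != "temperature_C":
        raise InvalidDesignError("profile is not a temperature profile")
    est = InactivationArrheniusRegressor(
        t0=cfg.get("t0", 313.15), n_starts=cfg.get("n_starts", 16),
        random_state=cfg.get("random_state", 0),
    )
    est.fit((kcatKm_profile.x + 273.15).reshape(-1, 1), kcatKm_profile.values)
    return est


@dataclass(frozen=True)
class OptimumResult:
    temperature_K: float
    value: float
    at_boundary: bool

    @property
    def temperature_C(self):
        return self.temperature_K - 273.15


def temperature_optimum(model, which: str, range_K) -> OptimumResult:
    """Argmax of the selected rate law on [lo, hi] K, refined to 0.01 K.

    A dense 0.01 K grid localizes the maximum; bounded scalar optimization
    refines it.  An optimum within 0.02 K of either end is boundary-flagged.
    """
    lo, hi = float(range_K[0]), float(range_K[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise InvalidParameterError("range must be a finite (lo, hi) with lo < hi")
    grid = np.arange(lo, hi + 0.005, 0.01)
    vals = predict_temperature_model(model, which, grid)
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if a < b:
        res = minimize_scalar(
            lambda t: -float(predict_temperature_model(model, which, t)),
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-4},
        )
        t_opt = float(res.x)
    else:
        t_opt = float(grid[i])
    at_boundary = (t_opt - lo) < 0.02 or (hi - t_opt) < 0.02
    if at_boundary:
        t_opt = lo if (t_opt - lo) < (hi - t_opt) else hi
    return OptimumResult(
        temperature_K=t_opt,
        value=float(predict_temperature_model(model, which, t_opt)),
        at_boundary=at_boundary,
    )


def thermostability_summary(table: ResidualActivityTable,
                            threshold: float = 0.95):
    """Highest preincubation temperature (degC) retaining >= threshold of the
    maximal activity, or None when no tested temperature qualifies."""
    if len(table) == 0:
        raise EmptyInputError("residual-activity table is empty")
    if not (0.0 < threshold <= 1.0):
        raise InvalidParameterError("threshold must lie in (0, 1]")
    f = table.frame
    ok = f[f["residual_activity"] >= threshold]
    if len(ok) == 0:
        return None
    return float(ok["preincubation_temp_C"].max())
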