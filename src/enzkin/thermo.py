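"""Transition-state thermodynamics: Eyring analysis and energy diagrams.

The Eyring equation, linearized as

    T ln(k/T) = T [ln(kB/hbar) + dS/R] - dH/R,

turns a rate-constant temperature series into an ordinary least-squares
problem: regressing y = T ln(k/T) on T gives slope s and intercept b with
dS = R (s - ln(kB/hbar)) and dH = -R b.  For a second-order constant such as
kcat/Km the resulting quantities depend on the 1 M standard state; they are
reported as-is and labelled accordingly by the caller.

Energy diagrams place each species of the acyl-enzyme scheme on a free-energy
ladder using Arrhenius barriers Ea = RT ln(A/k) under an assumed
pre-exponential factor A.  Ground-state levels are obtained by differencing
forward and backward barriers across each transition state, so they are
independent of A (A cancels in every difference); barrier heights shift
uniformly by RT ln(A'/A) when A changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .constants import DEFAULT_PREEXPONENTIAL, KB_OVER_HBAR, KCAL_TO_J, R
from .exceptions import (
    InvalidParameterError,
    InvalidRateError,
    NegativeBarrierError,
    UnderdeterminedError,
)
from .temperature import ElementaryRates


@dataclass(frozen=True)
class ActivationThermo:
    """Activation enthalpy (J mol^-1) and entropy (J mol^-1 K^-1)."""

    dh: float
    ds: float

    def dg_at(self, t):
        """Gibbs activation energy dG = dH - T dS at T (K)."""
        return self.dh - np.asarray(t, dtype=float) * self.ds

    def rate_at(self, t):
        """Eyring reconstruction k(T) = (kB T/hbar) e^{dS/R} e^{-dH/RT}."""
        t = np.asarray(t, dtype=float)
        return KB_OVER_HBAR * t * np.exp(self.ds / R) * np.exp(-self.dh / (R * t))


class EyringRegressor(RegressorMixin, BaseEstimator):
    """OLS Eyring fit of a (T, k) series.

    ``fit(X, y)`` takes X = temperatures in K (one column) and y = rate
    constants (s^-1).  Fitted attributes: ``dh_`` (J mol^-1), ``ds_``
    (J mol^-1 K^-1), ``thermo_`` (:class:`ActivationThermo`), ``slope_``,
    ``intercept_``.  ``predict`` reconstructs k(T).
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        t = X[:, 0]
        k = np.asarray(y, dtype=float)
        if np.any(k <= 0):
            raise InvalidRateError("all rate constants must be positive")
        if np.any(t <= 0):
            raise InvalidParameterError("temperatures must be in K and positive")
        if len(np.unique(t)) < 2:
            raise UnderdeterminedError(
                "Eyring fit needs at least two distinct temperatures"
            )
        yy = t * np.log(k / t)
        slope, intercept = np.polyfit(t, yy, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.ds_ = float(R * (slope - np.log(KB_OVER_HBAR)))
        self.dh_ = float(-R * intercept)
        self.thermo_ = ActivationThermo(dh=self.dh_, ds=self.ds_)
        self.residuals_ = yy - (slope * t + intercept)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "thermo_")
        X = check_array(X)
        return self.thermo_.rate_at(X[:, 0])


def eyring_fit(k_series) -> ActivationThermo:
    """Fit the Eyring line to an iterable of (T_K, k) pairs."""
    arr = np.asarray(list(k_series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidParameterError("k_series must be (T, k) pairs")
    est = EyringRegressor().fit(arr[:, [0]], arr[:, 1])
    return est.thermo_


def activation_energy_from_rate(k: float, A: float = DEFAULT_PREEXPONENTIAL,
                                t: float = 313.15) -> float:
    """Arrhenius barrier Ea = RT ln(A/k), J mol^-1.

    Physically admissible only for 0 < k <= A; a faster-than-prefactor rate
    would imply a negative barrier.
    """
    if not A > 0:
        raise InvalidParameterError("pre-exponential factor must be positive")
    if not k > 0:
        raise InvalidRateError("rate constant must be positive")
    if k > A:
        raise NegativeBarrierError(
            f"k={k:g} exceeds the assumed pre-exponential A={A:g}"
        )
    return R * t * np.log(A / k)


_SPECIES = ("E+S", "TS1", "ES", "TS2", "E_acyl", "TS3")


@dataclass(frozen=True)
class EnergyDiagram:
    """Free-energy levels (kcal mol^-1) of the acyl-enzyme reaction course.

    ``levels`` maps species to levels with E+S fixed at zero.  Because the
    reverse of the acylation step is not modelled, the acyl-enzyme level is
    placed below TS2 by the deacylation barrier Ea(k3); TS3 therefore
    coincides with TS2 and the diagram ends at that barrier.
    """

    levels: dict
    preexponential: float
    temperature_K: float

    def species(self):
        return _SPECIES

    def to_text(self) -> str:
        lines = [f"# energy diagram at T = {self.temperature_K:.2f} K, "
                 f"A = {self.preexponential:g} s^-1",
                 "species\tlevel_kcal_per_mol"]
        for sp in _SPECIES:
            lines.append(f"{sp}\t{self.levels[sp]:.4f}")
        return "\n".join(lines) + "\n"


def build_energy_diagram(rates: ElementaryRates, t: float = 313.15,
                         A: float = DEFAULT_PREEXPONENTIAL) -> EnergyDiagram:
    """Construct the reaction energy diagram from elementary rates at T.

    Barriers come from Ea = RT ln(A/k) per rate constant; ground states are
    differences of forward/backward barriers: ES = Ea(k1) - Ea(k-1)
    (equivalently RT ln(k-1/k1)), E_acyl = TS2 - Ea(k3).
    """
    ea = {name: activation_energy_from_rate(k, A, t) for name, k in (
        ("k1", float(rates.k1(t))), ("km1", float(rates.km1(t))),
        ("k2", float(rates.k2(t))), ("k3", float(rates.k3(t))),
    )}
    ts1 = ea["k1"]
    es = ea["k1"] - ea["km1"]
    ts2 = es + ea["k2"]
    e_acyl = ts2 - ea["k3"]
    ts3 = e_acyl + ea["k3"]
    levels = {"E+S": 0.0, "TS1": ts1, "ES": es, "TS2": ts2,
              "E_acyl": e_acyl, "TS3": ts3}
    levels = {k: v / KCAL_TO_J for k, v in levels.items()}
    return EnergyDiagram(levels=levels, preexponential=A, temperature_K=t)
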