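"""Michaelis-Menten estimation and salt-effect comparisons.

The central object is :class:`MichaelisMentenRegressor`, a scikit-learn style
estimator fitting v = Vmax.[S]/(Km + [S]) by nonlinear least squares in
log-parameter space (which enforces positivity).  Unit conventions follow the
field's reporting style for chromogenic ester assays: kcat in s^-1, Km in mM,
kcat/Km in M^-1 s^-1 (the mM -> M factor of 10^3 is applied exactly once, in
:attr:`MichaelisMentenParams.kcat_over_km`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import RateDataset
from .exceptions import (
    FitError,
    InvalidComparisonError,
    InvalidDesignError,
    InvalidParameterError,
)


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Fitted turnover and Michaelis constants for one substrate.

    kcat in s^-1, km_mM in mM.  The catalytic efficiency kcat/Km (M^-1 s^-1)
    is always derived from these two, never stored independently.
    """

    substrate_name: str
    kcat: float
    km_mM: float
    kcat_se: float = float("nan")
    km_se: float = float("nan")

    def __post_init__(self):
        if not (self.kcat > 0 and self.km_mM > 0):
            raise InvalidParameterError(
                f"kcat and Km must be positive, got kcat={self.kcat}, "
                f"Km={self.km_mM} mM"
            )

    @property
    def kcat_over_km(self) -> float:
        """Catalytic efficiency, M^-1 s^-1."""
        return self.kcat / (self.km_mM * 1e-3)

    @property
    def kcat_over_km_se(self) -> float:
        # first-order propagation assuming independent errors
        rel = np.hypot(self.kcat_se / self.kcat, self.km_se / self.km_mM)
        return self.kcat_over_km * rel

    def velocity(self, s_mM, enzyme_conc_nM):
        """Predicted initial velocity (M s^-1) at [S] (mM), [E] (nM)."""
        s = np.asarray(s_mM, dtype=float)
        e_molar = enzyme_conc_nM * 1e-9
        return self.kcat * e_molar * s / (self.km_mM + s)


@dataclass(frozen=True)
class SaltEffectReport:
    """Treated/control parameter ratios (percent) for one salt condition."""

    salt: str
    concentration_mM: float
    substrate_name: str
    ratio_kcatKm: float
    ratio_kcat: float
    ratio_Km: float


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares Michaelis-Menten fit.

    Parameters
    ----------
    enzyme_conc_nM : float
        Active enzyme concentration of the assay; converts Vmax to kcat.
    relative_weighting : bool, default False
        If True, residuals are divided by the model value (constant relative
        error); the default is unweighted least squares.
    substrate_name : str, default "substrate"

    Attributes (after ``fit``)
    --------------------------
    vmax_ : float, M s^-1
    kcat_ : float, s^-1
    km_ : float, mM
    kcat_se_, km_se_ : asymptotic standard errors
    params_ : MichaelisMentenParams
    saturation_warning_ : True when max [S] < fitted Km (plateau never
        approached; kcat poorly constrained).
    """

    def __init__(self, enzyme_conc_nM=850.0, relative_weighting=False,
                 substrate_name="substrate"):
        self.enzyme_conc_nM = enzyme_conc_nM
        self.relative_weighting = relative_weighting
        self.substrate_name = substrate_name

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        if self.enzyme_conc_nM is None or self.enzyme_conc_nM <= 0:
            raise InvalidParameterError("enzyme_conc_nM must be positive")
        s = X[:, 0]
        if (s < 0).any():
            raise InvalidParameterError("substrate concentrations must be >= 0")
        if len(np.unique(s[s > 0])) < 4:
            raise InvalidDesignError(
                "need at least 4 distinct nonzero [S] for a full fit"
            )
        if (y <= 0).all():
            raise FitError("all velocities non-positive; nothing to fit")

        vmax0 = float(np.max(y))
        # [S] whose velocity is nearest half-max is the natural Km guess
        km0 = float(s[np.argmin(np.abs(y - vmax0 / 2.0))])
        if km0 <= 0:
            km0 = float(np.median(s[s > 0]))

        def residuals(theta):
            vmax, km = np.exp(theta)
            pred = vmax * s / (km + s)
            res = pred - y
            if self.relative_weighting:
                res = res / np.maximum(pred, 1e-300)
            return res

        sol = least_squares(residuals, x0=np.log([vmax0, km0]), method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise FitError(
                "Michaelis-Menten fit did not converge",
                diagnostics={"message": sol.message, "cost": float(sol.cost)},
            )
        vmax, km = np.exp(sol.x)
        se_log = _asymptotic_se(sol)
        e_molar = self.enzyme_conc_nM * 1e-9

        self.vmax_ = float(vmax)
        self.km_ = float(km)
        self.kcat_ = float(vmax / e_molar)
        # delta method: se(p) = p * se(log p)
        self.kcat_se_ = float(self.kcat_ * se_log[0])
        self.km_se_ = float(km * se_log[1])
        self.saturation_warning_ = bool(np.max(s) < km)
        if self.saturation_warning_:
            warnings.warn(
                f"saturation never approached (max [S]={np.max(s):g} mM < "
                f"fitted Km={km:g} mM); kcat weakly constrained"
            )
        self.params_ = MichaelisMentenParams(
            substrate_name=self.substrate_name, kcat=self.kcat_,
            km_mM=self.km_, kcat_se=self.kcat_se_, km_se=self.km_se_,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "km_")
        X = check_array(X)
        s = X[:, 0]
        return self.vmax_ * s / (self.km_ + s)


def _asymptotic_se(sol):
    """Standard errors of least_squares parameters from the Jacobian."""
    _, n_par = sol.jac.shape
    dof = max(len(sol.fun) - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def fit_michaelis_menten(data: RateDataset, substrate: Optional[str] = None,
                         relative_weighting=False) -> MichaelisMentenParams:
    """Fit the Michaelis-Menten model to one substrate's pooled replicates.

    The dataset must contain a single substrate (after optional filtering),
    a single pH, temperature and enzyme concentration.  Replicates are fitted
    pooled, not averaged first.
    """
    frame = data.frame
    if substrate is not None:
        frame = frame[frame["substrate_name"] == substrate]
    if len(frame) == 0:
        raise InvalidDesignError("no rows to fit (empty dataset or filter)")
    for col in ("substrate_name", "pH", "temperature_C", "enzyme_conc_nM"):
        if frame[col].nunique() != 1:
            raise InvalidDesignError(
                f"fit requires a single value of {col}; found "
                f"{sorted(frame[col].unique())}"
            )
    name = frame["substrate_name"].iloc[0]
    enzyme = float(frame["enzyme_conc_nM"].iloc[0])
    est = MichaelisMentenRegressor(
        enzyme_conc_nM=enzyme, relative_weighting=relative_weighting,
        substrate_name=str(name),
    )
    est.fit(frame[["substrate_conc_mM"]].to_numpy(float),
            frame["velocity"].to_numpy(float))
    return est.params_


def estimate_from_regimes(low_S_data: RateDataset, high_S_data: RateDataset,
                          km_guess_mM: Optional[float] = None) -> MichaelisMentenParams:
    """Two-regime protocol: kcat/Km from the linear low-[S] limit, kcat from
    the high-[S] plateau, Km derived as their quotient.

    Low regime: v ~ (kcat/Km).[E].[S], so the zero-intercept regression slope
    of v on [S] divided by [E] gives kcat/Km.  High regime: the plateau mean
    velocity divided by [E] gives kcat (with a small bias Km/(Km+[S])).
    """
    lo, hi = low_S_data.frame, high_S_data.frame
    if len(lo) == 0 or len(hi) == 0:
        raise InvalidDesignError("both regimes need data")
    name_lo = lo["substrate_name"].iloc[0]
    name_hi = hi["substrate_name"].iloc[0]
    if name_lo != name_hi:
        raise InvalidComparisonError(
            f"regimes measured on different substrates: {name_lo} vs {name_hi}"
        )
    if lo["substrate_conc_mM"].max() >= hi["substrate_conc_mM"].min():
        raise InvalidDesignError(
            "regime overlap: low-[S] concentrations must lie strictly below "
            "high-[S] concentrations"
        )
    if km_guess_mM is not None:
        if lo["substrate_conc_mM"].max() >= km_guess_mM:
            warnings.warn("low regime contains [S] >= declared Km guess")
        if hi["substrate_conc_mM"].min() <= km_guess_mM:
            warnings.warn("high regime contains [S] <= declared Km guess")

    e_lo = float(lo["enzyme_conc_nM"].iloc[0]) * 1e-9
    e_hi = float(hi["enzyme_conc_nM"].iloc[0]) * 1e-9
    s = lo["substrate_conc_mM"].to_numpy(float)
    v = lo["velocity"].to_numpy(float)
    slope = float(np.dot(s, v) / np.dot(s, s))  # zero-intercept OLS, per mM
    kcat_over_km = slope * 1e3 / e_lo           # M^-1 s^-1
    kcat = float(hi["velocity"].mean()) / e_hi  # s^-1
    km_mM = kcat / kcat_over_km * 1e3
    return MichaelisMentenParams(substrate_name=str(name_lo), kcat=kcat,
                                 km_mM=km_mM)


def compare_salt_effect(control: MichaelisMentenParams,
                        treated: MichaelisMentenParams,
                        salt: str, concentration_mM: float) -> SaltEffectReport:
    """Express a salt treatment as percent-of-control parameter ratios."""
    if control.substrate_name != treated.substrate_name:
        raise InvalidComparisonError(
            f"substrate mismatch: {control.substrate_name} vs "
            f"{treated.substrate_name}"
        )
    return SaltEffectReport(
        salt=salt,
        concentration_mM=concentration_mM,
        substrate_name=control.substrate_name,
        ratio_kcatKm=100.0 * treated.kcat_over_km / control.kcat_over_km,
        ratio_kcat=100.0 * treated.kcat / control.kcat,
        ratio_Km=100.0 * treated.km_mM / control.km_mM,
    )
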