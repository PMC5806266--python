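"""Bell-shaped pH dependence of kinetic parameters (two-pKa model).

Many hydrolases require one catalytic group deprotonated (pKa1, typically the
catalytic histidine) and another protonated (pKa2).  The observed parameter
then follows

    k_obs(pH) = k_lim / (1 + 10^(pKa1 - pH) + 10^(pH - pKa2)),

a unimodal, log-symmetric bell whose analytic maximum sits at the midpoint
(pKa1 + pKa2)/2.  :class:`PHProfileRegressor` fits (k_lim, pKa1, pKa2) by
nonlinear least squares with the ordering pKa1 < pKa2 enforced through the
reparameterization pKa2 = pKa1 + exp(theta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import ProfileDataset
from .exceptions import FitError, InvalidModelError
from .mm import _asymptotic_se


@dataclass(frozen=True)
class PHProfileModel:
    """Two-pKa model parameters for one profiled kinetic parameter.

    ``k_lim`` carries the units of that parameter (M^-1 s^-1 for kcat/Km,
    s^-1 for kcat).
    """

    k_lim: float
    pka1: float
    pka2: float
    parameter_kind: str = "kcatKm"  # kcatKm | kcat

    def __post_init__(self):
        if not self.k_lim > 0:
            raise InvalidModelError(f"k_lim must be positive, got {self.k_lim}")
        if not self.pka1 < self.pka2:
            raise InvalidModelError(
                f"requires pKa1 < pKa2, got {self.pka1} >= {self.pka2}"
            )

    def predict(self, pH):
        return predict_eq1(self, pH)

    @property
    def ph_optimum(self) -> float:
        return ph_optimum(self)


@dataclass(frozen=True)
class PHProfileFit:
    """A fitted two-pKa model with uncertainties and residual summary."""

    model: PHProfileModel
    k_lim_se: float
    pka1_se: float
    pka2_se: float
    rss: float
    n_obs: int
    narrow_separation_warning: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def ph_optimum(self) -> float:
        return self.model.ph_optimum


def predict_eq1(model: PHProfileModel, pH):
    """Evaluate the two-pKa rate law at the given pH value(s)."""
    ph = np.asarray(pH, dtype=float)
    return model.k_lim / (1.0 + 10.0 ** (model.pka1 - ph)
                          + 10.0 ** (ph - model.pka2))


def ph_optimum(model: PHProfileModel) -> float:
    """Analytic pH of maximal activity: the pKa midpoint.

    Setting d k_obs/d pH = 0 gives 10^(pKa1-pH) = 10^(pH-pKa2), i.e.
    pH = (pKa1 + pKa2)/2.
    """
    return 0.5 * (model.pka1 + model.pka2)


class PHProfileRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the two-pKa bell to a k_obs-vs-pH profile.

    Parameters
    ----------
    parameter_kind : {"kcatKm", "kcat"}
        Bookkeeping label for the profiled parameter.
    min_separation_warn : float, default 0.3
        Below this fitted pKa separation the limiting rate and the pKa pair
        become strongly correlated; the fit is returned but flagged.

    Attributes (after ``fit``)
    --------------------------
    k_lim_, pka1_, pka2_ : fitted parameters
    ph_optimum_ : (pka1_ + pka2_)/2
    model_ : PHProfileModel ; fit_ : PHProfileFit
    """

    def __init__(self, parameter_kind="kcatKm", min_separation_warn=0.3):
        self.parameter_kind = parameter_kind
        self.min_separation_warn = min_separation_warn

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        ph = X[:, 0]
        if len(np.unique(ph)) < 6:
            warnings.warn("fewer than 6 distinct pH points; two-pKa fit may "
                          "be poorly constrained")
        if (y <= 0).all():
            raise FitError("all observed rates non-positive")
        order = np.argsort(ph)
        ph_s, y_s = ph[order], y[order]
        imax = int(np.argmax(y_s))
        if imax == 0 or imax == len(y_s) - 1:
            raise FitError(
                "profile maximum sits on the grid boundary: data cover only "
                "one flank of the bell",
                diagnostics={"argmax_pH": float(ph_s[imax])},
            )

        k0 = float(np.max(y_s))
        pka1_0, pka2_0 = _half_max_crossings(ph_s, y_s, imax)

        def residuals(theta):
            k_lim = np.exp(theta[0])
            pka1 = theta[1]
            pka2 = pka1 + np.exp(theta[2])
            return (k_lim / (1.0 + 10.0 ** (pka1 - ph)
                             + 10.0 ** (ph - pka2)) - y)

        x0 = np.array([np.log(k0), pka1_0,
                       np.log(max(pka2_0 - pka1_0, 0.2))])
        sol = least_squares(residuals, x0=x0, method="lm",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if not sol.success:
            raise FitError("two-pKa fit did not converge",
                           diagnostics={"message": sol.message})
        k_lim = float(np.exp(sol.x[0]))
        pka1 = float(sol.x[1])
        delta = float(np.exp(sol.x[2]))
        pka2 = pka1 + delta
        se = _asymptotic_se(sol)
        # delta method through the reparameterization
        k_lim_se = k_lim * se[0]
        pka1_se = se[1]
        pka2_se = float(np.hypot(se[1], delta * se[2]))

        narrow = delta < self.min_separation_warn
        if narrow:
            warnings.warn(
                f"pKa separation {delta:.2f} < {self.min_separation_warn}: "
                "k_lim and pKa estimates are strongly correlated"
            )
        self.k_lim_, self.pka1_, self.pka2_ = k_lim, pka1, pka2
        self.ph_optimum_ = 0.5 * (pka1 + pka2)
        self.model_ = PHProfileModel(k_lim, pka1, pka2, self.parameter_kind)
        self.fit_ = PHProfileFit(
            model=self.model_, k_lim_se=float(k_lim_se), pka1_se=float(pka1_se),
            pka2_se=pka2_se, rss=float(2.0 * sol.cost), n_obs=len(y),
            narrow_separation_warning=narrow,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return predict_eq1(self.model_, X[:, 0])


def _half_max_crossings(ph_s, y_s, imax):
    """Initial pKa guesses: pH of half-max crossing on each flank."""
    half = y_s[imax] / 2.0
    left = ph_s[: imax + 1][y_s[: imax + 1] <= half]
    right = ph_s[imax:][y_s[imax:] <= half]
    pka1_0 = float(left[-1]) if len(left) else float(ph_s[imax] - 1.0)
    pka2_0 = float(right[0]) if len(right) else float(ph_s[imax] + 1.0)
    if pka2_0 - pka1_0 < 0.2:
        pka1_0, pka2_0 = ph_s[imax] - 0.5, ph_s[imax] + 0.5
    return pka1_0, pka2_0


def fit_ph_profile(profile: ProfileDataset) -> PHProfileFit:
    """Fit the two-pKa model to a ProfileDataset (x_name must be 'pH')."""
    if len(profile) == 0:
        raise FitError("empty profile")
    if profile.frame["x_name"].iloc[0] != "pH":
        raise InvalidModelError("profile is not a pH profile")
    est = PHProfileRegressor(parameter_kind=profile.parameter_kind)
    est.fit(profile.frame[["x"]].to_numpy(float), profile.values)
    return est.fit_
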