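"""Reduction thermodynamics from temperature-dependent formal potentials.

With a non-isothermal cell (reference electrode thermostatted), the slope of
E0' against the working-cell temperature gives the reduction entropy
directly,

    dS_rc = S_red - S_ox = n F (dE0'/dT),

and the Gibbs-Helmholtz construction gives the reduction enthalpy as the
negative slope of E0'/T against 1/T.  The free energy at a reference
temperature follows from dG = dH - T dS = -n F E0'.  Across immobilization
conditions the enthalpic and entropic terms often move in opposition
(enthalpy/entropy compensation); a linear regression of dH on dS with
studentized-residual outlier flagging quantifies that.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import FARADAY
from .errors import LackOfFitWarning
from .types import CompensationResult, RedoxThermo

__all__ = [
    "RedoxThermoEstimator",
    "CompensationRegression",
    "fit_entropy",
    "fit_enthalpy",
    "thermo_summary",
    "compensation_regression",
]


def _as_table(table) -> tuple:
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns)
        T = np.asarray(table[cols[0]], dtype=float)
        E = np.asarray(table[cols[1]], dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        T, E = arr[:, 0], arr[:, 1]
    return T, E


def _check_grid(T: np.ndarray) -> None:
    if T.size < 3:
        raise ValueError("at least 3 (T, E) points are required")
    if T.max() - T.min() < 10.0:
        raise ValueError("temperature spread must be >= 10 K")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive kelvin")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple:
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.stderr, res.intercept_stderr


def _runs_test_warn(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> None:
    resid = y - (slope * x + intercept)
    if np.max(np.abs(resid)) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return  # numerically exact fit: sign pattern is round-off noise
    signs = np.sign(resid[resid != 0])
    if signs.size < 8:
        return
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n_pos = int(np.sum(signs > 0))
    n_neg = signs.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("regression residuals all share one sign; possible lack of fit",
                      LackOfFitWarning)
        return
    mu = 1 + 2 * n_pos * n_neg / (n_pos + n_neg)
    var = (2 * n_pos * n_neg * (2 * n_pos * n_neg - n_pos - n_neg)
           / ((n_pos + n_neg) ** 2 * (n_pos + n_neg - 1)))
    if var > 0 and abs(runs - mu) / np.sqrt(var) > 1.96:
        warnings.warn("runs test on residuals indicates non-linear lack of fit",
                      LackOfFitWarning)


class RedoxThermoEstimator(BaseEstimator, RegressorMixin):
    """Estimator for reduction thermodynamics from an E0'(T) series.

    Parameters
    ----------
    n : int
        Electrons exchanged.
    T_ref : float
        Reference temperature (K) at which the free energy is evaluated.
    condition_label : str
        Free-text label (SAM composition, pH, ...) carried into the summary.

    Attributes (after ``fit``)
    --------------------------
    dE_dT_ : float            slope of E0' vs T, V/K
    entropy_rc_ : float       n F dE0'/dT, J mol^-1 K^-1
    enthalpy_rc_ : float      -n F * slope(E0'/T vs 1/T), kJ mol^-1
    gibbs_rc_ : float         dH - T_ref dS, kJ mol^-1
    E_ref_ : float            fitted E0' at T_ref, V
    summary_ : RedoxThermo
    """

    def __init__(self, n: int = 1, T_ref: float = 298.15, condition_label: str = ""):
        self.n = n
        self.T_ref = T_ref
        self.condition_label = condition_label

    def fit(self, X, y=None):
        if y is None:
            T, E = _as_table(X)
        else:
            T = np.asarray(X, dtype=float).reshape(-1)
            E = np.asarray(y, dtype=float).reshape(-1)
        _check_grid(T)
        nF = self.n * FARADAY

        slope, intercept, slope_se, _ = _ols_line(T, E)
        _runs_test_warn(T, E, slope, intercept)
        self.dE_dT_ = slope
        self.dE_dT_se_ = slope_se
        self.entropy_rc_ = nF * slope
        self.entropy_rc_se_ = nF * slope_se
        self.E_ref_ = slope * self.T_ref + intercept

        gh_slope, _, gh_se, _ = _ols_line(1.0 / T, E / T)
        self.enthalpy_rc_ = -nF * gh_slope / 1000.0
        self.enthalpy_rc_se_ = nF * gh_se / 1000.0

        self.gibbs_rc_ = self.enthalpy_rc_ - self.T_ref * self.entropy_rc_ / 1000.0
        self.summary_ = RedoxThermo(
            E_ref=self.E_ref_, T_ref=self.T_ref, n=self.n,
            dE_dT=self.dE_dT_, dE_dT_se=self.dE_dT_se_,
            entropy_rc=self.entropy_rc_, entropy_rc_se=self.entropy_rc_se_,
            enthalpy_rc=self.enthalpy_rc_, enthalpy_rc_se=self.enthalpy_rc_se_,
            gibbs_rc=self.gibbs_rc_, condition_label=self.condition_label)
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return self.E_ref_ + self.dE_dT_ * (T - self.T_ref)


class CompensationRegression(BaseEstimator, RegressorMixin):
    """OLS of reduction enthalpy on reduction entropy with outlier flagging.

    Outliers are flagged sequentially: the point with the largest externally
    studentized residual above ``threshold`` is set aside, the line is
    refitted, and the test repeats until nothing exceeds the threshold (or
    fewer than 4 points would remain).  Sequential testing avoids the
    masking that a one-shot rule suffers when two outliers inflate the
    residual variance together.  With ``refit=True`` the line refitted on
    the unflagged points is reported alongside the full-sample fit.
    """

    def __init__(self, threshold: float = 2.5, refit: bool = True):
        self.threshold = threshold
        self.refit = refit

    def fit(self, X, y):
        dS = np.asarray(X, dtype=float).reshape(-1)
        dH = np.asarray(y, dtype=float).reshape(-1)
        if dS.size < 4:
            raise ValueError("compensation regression needs >= 4 points")
        if np.ptp(dS) == 0:
            raise ValueError("entropy values are degenerate (zero variance)")
        design = sm.add_constant(dS)
        ols = sm.OLS(dH, design).fit()
        student = np.nan_to_num(ols.get_influence().resid_studentized_external)

        scale = max(1.0, float(np.max(np.abs(dH))))
        mask = np.zeros(dS.size, dtype=bool)
        while (~mask).sum() > 4:
            keep = ~mask
            sub = sm.OLS(dH[keep], sm.add_constant(dS[keep])).fit()
            if np.sqrt(sub.ssr / max(keep.sum() - 2, 1)) < 1e-9 * scale:
                break  # numerically perfect line: nothing to flag
            t_sub = np.nan_to_num(sub.get_influence().resid_studentized_external)
            worst = int(np.argmax(np.abs(t_sub)))
            if abs(t_sub[worst]) <= self.threshold:
                break
            mask[np.flatnonzero(keep)[worst]] = True
        self.slope_ = float(ols.params[1])
        self.intercept_ = float(ols.params[0])
        self.slope_se_ = float(ols.bse[1])
        self.intercept_se_ = float(ols.bse[0])
        self.studentized_residuals_ = np.asarray(student, dtype=float)
        self.outlier_mask_ = mask
        refit_slope = refit_intercept = None
        if self.refit and mask.any() and (~mask).sum() >= 3:
            keep = ~mask
            ols2 = sm.OLS(dH[keep], sm.add_constant(dS[keep])).fit()
            refit_slope, refit_intercept = float(ols2.params[1]), float(ols2.params[0])
        self.result_ = CompensationResult(
            slope=self.slope_, slope_se=self.slope_se_,
            intercept=self.intercept_, intercept_se=self.intercept_se_,
            studentized_residuals=self.studentized_residuals_,
            outlier_mask=mask, refit_slope=refit_slope,
            refit_intercept=refit_intercept)
        return self

    def predict(self, X):
        dS = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * dS


def fit_entropy(table, n: int = 1):
    """Reduction entropy from the slope of E0' vs T.

    Returns ``(dE_dT, entropy_rc)`` where ``entropy_rc = n F dE0'/dT`` in
    J mol^-1 K^-1; standard errors are available from
    :class:`RedoxThermoEstimator`.
    """
    est = RedoxThermoEstimator(n=n).fit(table)
    return est.dE_dT_, est.entropy_rc_


def fit_enthalpy(table, n: int = 1) -> float:
    """Reduction enthalpy (kJ mol^-1) as -nF times the slope of E0'/T vs 1/T."""
    est = RedoxThermoEstimator(n=n).fit(table)
    return est.enthalpy_rc_


def thermo_summary(table, n: int = 1, T_ref: float = 298.15,
                   condition_label: str = "") -> RedoxThermo:
    """Bundle the entropy and enthalpy fits into a :class:`RedoxThermo` record."""
    est = RedoxThermoEstimator(n=n, T_ref=T_ref, condition_label=condition_label)
    return est.fit(table).summary_


def compensation_regression(results: Sequence[RedoxThermo],
                            threshold: float = 2.5,
                            refit: bool = True) -> CompensationResult:
    """Enthalpy/entropy compensation analysis across a series of conditions."""
    dS = np.array([r.entropy_rc for r in results])
    dH = np.array([r.enthalpy_rc for r in results])
    return CompensationRegression(threshold=threshold, refit=refit).fit(dS, dH).result_
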