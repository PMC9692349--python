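"""pH dependence of the formal potential: coupled acid-base equilibria.

For a redox couple whose reduction is coupled to proton uptake at up to
three sites, the formal potential follows

    E0'(pH) = E_lowpH + c * sum_i log10[(Ka_red,i + [H+]) / (Ka_ox,i + [H+])]

with ``[H+] = 10^-pH``, ``c`` the Nernst coefficient (0.059 V per decade at
room temperature) and ``Ka_ox,i > Ka_red,i`` (i.e. pKa_red,i > pKa_ox,i:
the reduced protein binds protons more tightly).  Between a well-separated
pair the local slope is -c per pH unit per proton; the apparent proton
uptake is the negative slope divided by c.

Fitting uses bounded nonlinear least squares with multi-start, the pair
ordering being enforced through the parameterization
``pKa_red = pKa_ox + exp(delta)``.
"""
from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, FitBoundaryWarning
from .types import PhFitResult, PhTitrationModel

__all__ = [
    "eval_ph_model",
    "local_slope",
    "proton_uptake",
    "PhTitrationEstimator",
    "fit_ph_model",
    "select_n_equilibria",
    "bootstrap_ph_fit",
]

_PKA_LO, _PKA_HI = 2.0, 13.0
_DELTA_LO, _DELTA_HI = np.log(1e-2), np.log(11.0)


def _check_ph(pH) -> np.ndarray:
    pH = np.asarray(pH, dtype=float)
    if np.any(pH < 0.0) or np.any(pH > 14.0):
        raise ValueError("pH must lie in [0, 14]")
    return pH


def _model_curve(pH: np.ndarray, e_low: float, pka_ox: np.ndarray,
                 pka_red: np.ndarray, c: float) -> np.ndarray:
    h = 10.0 ** (-pH[..., None])
    ka_ox = 10.0 ** (-np.asarray(pka_ox))
    ka_red = 10.0 ** (-np.asarray(pka_red))
    return e_low + c * np.sum(np.log10((ka_red + h) / (ka_ox + h)), axis=-1)


def eval_ph_model(model: PhTitrationModel, pH):
    """Formal potential at the given pH value(s), V."""
    pH = _check_ph(pH)
    ox = np.array([p[0] for p in model.equilibria])
    red = np.array([p[1] for p in model.equilibria])
    out = _model_curve(pH, model.E_lowpH, ox, red, model.nernst_coefficient)
    return float(out) if np.ndim(pH) == 0 else out


def local_slope(model: PhTitrationModel, pH):
    """Analytic dE0'/dpH (V per pH unit): -c * sum_i (f_red,i - f_ox,i)
    with ``f = [H+]/(Ka + [H+])`` the protonated fraction of each site."""
    pH = _check_ph(pH)
    h = 10.0 ** (-np.asarray(pH)[..., None])
    ox = 10.0 ** (-np.array([p[0] for p in model.equilibria]))
    red = 10.0 ** (-np.array([p[1] for p in model.equilibria]))
    f_red = h / (red + h)
    f_ox = h / (ox + h)
    out = -model.nernst_coefficient * np.sum(f_red - f_ox, axis=-1)
    return float(out) if np.ndim(pH) == 0 else out


def proton_uptake(model: PhTitrationModel, pH):
    """Apparent number of protons taken up on reduction at this pH,
    bounded in [0, n_equilibria]."""
    slope = local_slope(model, pH)
    return -slope / model.nernst_coefficient


def _unpack(theta: np.ndarray, n_eq: int):
    e_low = theta[0]
    pka_ox = theta[1:1 + n_eq]
    pka_red = pka_ox + np.exp(theta[1 + n_eq:1 + 2 * n_eq])
    return e_low, pka_ox, pka_red


class PhTitrationEstimator(BaseEstimator, RegressorMixin):
    """Multi-start bounded least-squares fit of the E0'(pH) model.

    Parameters
    ----------
    n_equilibria : int
        Number of coupled acid-base equilibria (1-3).
    nernst_coefficient : float
        V per decade; fixed during the fit (0.059 by default, matching the
        room-temperature Nernst slope convention).
    n_starts : int
        Number of seeded random multi-starts; pKa_ox starts are uniform in
        [3, 12] (sorted so pairs stay ordered), pKa gaps start in [0.5, 3].
    random_state : int
        Seed for the start generator.

    Attributes (after ``fit``)
    --------------------------
    model_ : PhTitrationModel      best-fit model (pairs sorted by mean pKa)
    stderr_ : dict                 Jacobian-based standard errors per parameter
    result_ : PhFitResult
    """

    def __init__(self, n_equilibria: int = 3, nernst_coefficient: float = 0.059,
                 n_starts: int = 50, random_state: int = 0,
                 temperature: float = 293.15):
        self.n_equilibria = n_equilibria
        self.nernst_coefficient = nernst_coefficient
        self.n_starts = n_starts
        self.random_state = random_state
        self.temperature = temperature

    def _fit_one(self, theta0, pH, E, bounds):
        n_eq = self.n_equilibria
        c = self.nernst_coefficient

        def resid(theta):
            e_low, ox, red = _unpack(theta, n_eq)
            return _model_curve(pH, e_low, ox, red, c) - E

        return least_squares(resid, theta0, bounds=bounds, method="trf",
                             xtol=1e-12, ftol=1e-12, gtol=1e-12)

    def fit(self, X, y=None):
        if y is None:
            df = pd.DataFrame(X)
            pH = np.asarray(df.iloc[:, 0], dtype=float)
            E = np.asarray(df.iloc[:, 1], dtype=float)
        else:
            pH = np.asarray(X, dtype=float).reshape(-1)
            E = np.asarray(y, dtype=float).reshape(-1)
        _check_ph(pH)
        n_eq = int(self.n_equilibria)
        if n_eq not in (1, 2, 3):
            raise ValueError("n_equilibria must be 1, 2 or 3")
        if pH.size < 3 + 2 * n_eq:
            raise ValueError(f"need >= {3 + 2 * n_eq} points for {n_eq} equilibria")
        if np.ptp(pH) < 3.0:
            raise ValueError("pH values must span >= 3 pH units")

        lo = np.r_[-np.inf, np.full(n_eq, _PKA_LO), np.full(n_eq, _DELTA_LO)]
        hi = np.r_[np.inf, np.full(n_eq, _PKA_HI), np.full(n_eq, _DELTA_HI)]
        rng = np.random.default_rng(self.random_state)

        starts = []
        for _ in range(int(self.n_starts)):
            pka0 = np.sort(rng.uniform(3.0, 12.0, n_eq))
            gap0 = np.log(rng.uniform(0.5, 3.0, n_eq))
            starts.append(np.r_[E.max(), pka0, gap0])

        best = None
        objectives = []
        for theta0 in starts:
            try:
                sol = self._fit_one(theta0, pH, E, (lo, hi))
            except Exception:
                objectives.append(np.inf)
                continue
            obj = 2.0 * sol.cost  # sum of squared residuals
            objectives.append(obj if sol.success or np.isfinite(obj) else np.inf)
            if not np.isfinite(obj):
                continue
            if best is None or obj < best[0] - 1e-15 or (
                    abs(obj - best[0]) <= 1e-15
                    and _unpack(sol.x, n_eq)[1][0] < _unpack(best[1].x, n_eq)[1][0]):
                best = (obj, sol)
        if best is None:
            raise ConvergenceError("no multi-start converged", partial=None)
        obj, sol = best

        e_low, pka_ox, pka_red = _unpack(sol.x, n_eq)
        # canonical order: by the mean pKa of each pair — stable even when
        # two oxidized-state pKa's nearly coincide (overlapping equilibria)
        order = np.argsort(pka_ox + pka_red)
        pka_ox, pka_red = pka_ox[order], pka_red[order]

        at_bounds = []
        for i, (o, r) in enumerate(zip(pka_ox, pka_red)):
            if o <= _PKA_LO + 1e-3 or o >= _PKA_HI - 1e-3:
                at_bounds.append(f"pKa{i + 1}ox")
            if r >= _PKA_HI:
                at_bounds.append(f"pKa{i + 1}red")
        if at_bounds:
            warnings.warn(f"fitted parameters at bounds: {', '.join(at_bounds)}",
                          FitBoundaryWarning)

        dof = max(pH.size - sol.x.size, 1)
        rms = float(np.sqrt(obj / pH.size))
        s2 = obj / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se_theta = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se_theta = np.full(sol.x.size, np.nan)
        # delta-method SEs on pKa_red = pKa_ox + exp(delta)
        se = {"E_lowpH": se_theta[0]}
        for i in range(n_eq):
            j = order[i]
            se[f"pKa{i + 1}ox"] = se_theta[1 + j]
            gap = np.exp(sol.x[1 + n_eq + j])
            var_red = se_theta[1 + j] ** 2 + (gap * se_theta[1 + n_eq + j]) ** 2
            se[f"pKa{i + 1}red"] = float(np.sqrt(var_red))

        # clip boundary overshoot of the reparameterized pKa_red
        model = PhTitrationModel(
            E_lowpH=float(e_low),
            equilibria=[(float(o), float(min(r, _PKA_HI))) for o, r in zip(pka_ox, pka_red)],
            nernst_coefficient=self.nernst_coefficient,
            temperature=self.temperature)
        self.model_ = model
        self.stderr_ = se
        self.result_ = PhFitResult(
            model=model, stderr=se, residual_rms=rms, n_equilibria=n_eq,
            n_points=pH.size, objective=obj,
            multistart_objectives=np.asarray(objectives),
            at_bounds=at_bounds)
        return self

    def predict(self, X):
        pH = np.asarray(X, dtype=float).reshape(-1)
        return eval_ph_model(self.model_, pH)


def fit_ph_model(table, n_equilibria: int = 3, n_starts: int = 50,
                 nernst_coefficient: float = 0.059,
                 random_state: int = 0) -> PhFitResult:
    """Fit the E0'(pH) model to a (pH, E) table; see
    :class:`PhTitrationEstimator` for the algorithm."""
    est = PhTitrationEstimator(n_equilibria=n_equilibria, n_starts=n_starts,
                               nernst_coefficient=nernst_coefficient,
                               random_state=random_state)
    return est.fit(table).result_


def select_n_equilibria(table, n_starts: int = 30, random_state: int = 0):
    """Fit 1-, 2- and 3-equilibria models and select by small-sample AICc.

    Returns ``(best_n, {n: PhFitResult})``; models whose preconditions the
    data cannot support are skipped.
    """
    fits = {}
    for n_eq in (1, 2, 3):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FitBoundaryWarning)
                fits[n_eq] = fit_ph_model(table, n_equilibria=n_eq,
                                          n_starts=n_starts,
                                          random_state=random_state)
        except (ValueError, ConvergenceError):
            continue
    if not fits:
        raise ConvergenceError("no model size could be fitted")
    best_n = min(fits, key=lambda k: fits[k].aicc)
    return best_n, fits


def bootstrap_ph_fit(table, n_equilibria: int = 3, n_boot: int = 200,
                     n_starts: int = 5, random_state: int = 0) -> dict:
    """Residual-resampling bootstrap standard errors for the pH-model fit.

    Refits use the point estimate as a warm start plus a few random starts;
    returns per-parameter SEs keyed like ``PhFitResult.stderr``.  Overlapping
    equilibria make some parameters weakly identified — the bootstrap makes
    that visible rather than hiding it.
    """
    df = pd.DataFrame(table)
    pH = np.asarray(df.iloc[:, 0], dtype=float)
    E = np.asarray(df.iloc[:, 1], dtype=float)
    point = fit_ph_model(np.c_[pH, E], n_equilibria=n_equilibria,
                         n_starts=50, random_state=random_state)
    fitted = eval_ph_model(point.model, pH)
    resid = E - fitted
    resid = resid - resid.mean()
    rng = np.random.default_rng(random_state)

    samples: dict = {k: [] for k in point.stderr}
    for _ in range(n_boot):
        E_b = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FitBoundaryWarning)
                fit_b = fit_ph_model(np.c_[pH, E_b], n_equilibria=n_equilibria,
                                     n_starts=n_starts,
                                     random_state=int(rng.integers(2 ** 31 - 1)))
        except ConvergenceError:
            continue
        samples["E_lowpH"].append(fit_b.model.E_lowpH)
        for i, (o, r) in enumerate(fit_b.model.equilibria):
            samples[f"pKa{i + 1}ox"].append(o)
            samples[f"pKa{i + 1}red"].append(r)
    return {k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
            for k, v in samples.items()}
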