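"""Heterogeneous electron-transfer kinetics of adsorbed redox couples.

The peak separation of a surface-confined couple grows with the
dimensionless sweep parameter ``m_inv = (F/RT) * (nu/ks)`` (Laviron's
trumpet plot).  The package builds the working curve
``dEp*nF/(RT)`` vs ``m_inv`` numerically from its own surface
Butler-Volmer simulator and inverts it per scan rate to estimate ``ks``;
alternatively, in the irreversible regime (dEp > 200/n mV) the linear
branches ``Ep vs ln(nu)`` give the transfer coefficient from their slopes
and ``ks`` from the intercept condition at ``Ep = E0'``.

Temperature-dependent rate constants give the activation enthalpy through
the Arrhenius slope of ``ln ks`` vs ``1/T``; with a negligible activation
entropy the Marcus relation ``lambda = 4*dH_act`` gives the reorganization
energy, and the tunneling expression

    ln ks = ln nu0 - beta * (r - r0) - dH_act/(RT)

bounds the distance between the film surface and the redox center once the
through-monolayer tunneling distance is subtracted.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .constants import BOLTZMANN, FARADAY, GAS_CONSTANT, PLANCK
from .errors import DistanceWarning, KineticsWarning
from .types import ETKinetics, KsExtraction, LavironWorkingCurve, TrumpetData

__all__ = [
    "build_working_curve",
    "LavironKsEstimator",
    "ArrheniusEstimator",
    "extract_ks",
    "arrhenius_activation",
    "marcus_lambda",
    "prefactor_kT_over_h",
    "tunneling_distance_interval",
    "et_kinetics_summary",
]

_MIN_DEP_V = 0.005  # rows below 5 mV separation are effectively reversible
_IRREV_DEP_V = 0.200  # irreversible-branch threshold (divided by n)

_CURVE_CACHE: dict = {}


def _default_m_inv_grid() -> np.ndarray:
    return np.geomspace(0.05, 200.0, 56)


def build_working_curve(alpha: float = 0.5,
                        m_inv_grid: Optional[Sequence[float]] = None,
                        cache_path: Optional[str] = None) -> LavironWorkingCurve:
    """Numerically generate the trumpet-plot working curve for one alpha.

    Each grid point is one noiseless, capacitance-free surface CV simulated
    at the corresponding ``nu/ks`` ratio, reduced to its dimensionless peak
    separation.  Curves are memoized in-process; ``cache_path`` additionally
    persists/reads the table as CSV.
    """
    from .processing import find_peaks
    from .simulate import simulate_surface_cv
    from .types import SimulationConfig

    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    grid = np.asarray(_default_m_inv_grid() if m_inv_grid is None else list(m_inv_grid),
                      dtype=float)
    key = (round(alpha, 6), grid.tobytes())
    if key in _CURVE_CACHE:
        return _CURVE_CACHE[key]
    if cache_path is not None and Path(cache_path).exists():
        df = pd.read_csv(cache_path)
        curve = LavironWorkingCurve(alpha=alpha,
                                    m_inv=df["m_inv"].to_numpy(),
                                    delta_ep_dimless=df["delta_ep_dimless"].to_numpy())
        _CURVE_CACHE[key] = curve
        return curve

    T = 298.15
    f = FARADAY / (GAS_CONSTANT * T)
    ks = 1.0
    deps = []
    for m_inv in grid:
        nu = m_inv * ks / f
        shift = np.log(max(m_inv, 1.0) + 1.0) / (f * min(alpha, 1.0 - alpha))
        half_window = min(0.25 + shift, 0.9)
        cfg = SimulationConfig(
            formal_potential=0.0, ks=ks, alpha=alpha, coverage_total=1e-11,
            scan_rate=nu, e_start=-half_window, e_switch=half_window,
            temperature=T, double_layer_capacitance=0.0, noise_sd=0.0,
            potential_step=1e-4)
        vg, _ = simulate_surface_cv(cfg)
        peaks = find_peaks(vg)
        deps.append(peaks.delta_Ep * f)
    deps = np.asarray(deps)
    keep = np.diff(deps, prepend=-np.inf) > 0  # guard tiny numerical wiggles
    curve = LavironWorkingCurve(alpha=alpha, m_inv=grid[keep],
                                delta_ep_dimless=deps[keep],
                                tolerance=1e-3)
    if cache_path is not None:
        pd.DataFrame({"m_inv": curve.m_inv,
                      "delta_ep_dimless": curve.delta_ep_dimless}).to_csv(
            cache_path, index=False)
    _CURVE_CACHE[key] = curve
    return curve


class LavironKsEstimator(BaseEstimator):
    """Extract the standard heterogeneous rate constant from a trumpet plot.

    Parameters
    ----------
    method : {'working_curve', 'irreversible_branch', 'auto'}
        'working_curve' inverts the numerically generated working curve row
        by row and aggregates by geometric mean (alpha fixed at ``alpha``);
        'irreversible_branch' fits the linear Ep-vs-ln(nu) branches, fitting
        alpha from the slopes; 'auto' uses the working curve and cross-checks
        against the irreversible branch when that applies, warning on > 25%
        disagreement.
    alpha : float
        Transfer coefficient assumed by the working-curve method.

    Attributes (after ``fit``)
    --------------------------
    ks_, ks_se_, alpha_, result_ (a :class:`~pfvkit.types.KsExtraction`)
    """

    def __init__(self, method: str = "working_curve", alpha: float = 0.5):
        self.method = method
        self.alpha = alpha

    def fit(self, X, y=None):
        trumpet = X if isinstance(X, TrumpetData) else TrumpetData(
            scan_rate=np.asarray(X)[:, 0], E_pa=np.asarray(X)[:, 1],
            E_pc=np.asarray(X)[:, 2], temperature=298.15)
        if self.method == "working_curve":
            res = self._fit_working_curve(trumpet)
        elif self.method == "irreversible_branch":
            res = self._fit_irreversible(trumpet)
        elif self.method == "auto":
            res = self._fit_working_curve(trumpet)
            try:
                res_ir = self._fit_irreversible(trumpet)
            except ValueError:
                res_ir = None
            if res_ir is not None and res.ks is not None:
                ratio = res_ir.ks / res.ks
                if not 0.75 <= ratio <= 1.0 / 0.75:
                    warnings.warn(
                        f"working-curve ({res.ks:.3g} s^-1) and irreversible-branch "
                        f"({res_ir.ks:.3g} s^-1) estimates disagree by more than 25%",
                        KineticsWarning)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.result_ = res
        self.ks_ = res.ks
        self.ks_se_ = res.ks_se
        self.alpha_ = res.alpha
        return self

    def _fit_working_curve(self, t: TrumpetData) -> KsExtraction:
        f = FARADAY * t.n_electrons / (GAS_CONSTANT * t.temperature)
        curve = build_working_curve(self.alpha)
        dep = t.delta_Ep
        if np.all(dep < _MIN_DEP_V):
            # every row is effectively reversible: only a lower bound on ks
            nu_max = t.scan_rate.max()
            m_inv_at_thr = curve.invert(_MIN_DEP_V * f)
            warnings.warn("all peak separations < 5 mV (reversible); "
                          "reporting a lower bound on ks only", KineticsWarning)
            return KsExtraction(ks=None, ks_se=None, alpha=self.alpha,
                                temperature=t.temperature, method="working_curve",
                                lower_bound_only=True,
                                ks_lower_bound=float(f * nu_max / m_inv_at_thr))
        ks_rows = []
        skipped_high = 0
        for nu, d in zip(t.scan_rate, dep):
            if d < _MIN_DEP_V:
                continue
            try:
                m_inv = curve.invert(d * f)
            except ValueError:
                skipped_high += 1
                continue
            ks_rows.append(f * nu / m_inv)
        if skipped_high:
            warnings.warn(f"{skipped_high} row(s) outside the working-curve range "
                          "were skipped", KineticsWarning)
        if not ks_rows:
            raise ValueError("no trumpet row falls in the working-curve range")
        ks_rows = np.asarray(ks_rows)
        log_ks = np.log(ks_rows)
        ks = float(np.exp(log_ks.mean()))
        se = float(ks * log_ks.std(ddof=1) / np.sqrt(log_ks.size)) \
            if log_ks.size > 1 else None
        return KsExtraction(ks=ks, ks_se=se, alpha=self.alpha,
                            temperature=t.temperature, method="working_curve",
                            per_row_ks=ks_rows, rows_used=int(ks_rows.size))

    def _fit_irreversible(self, t: TrumpetData) -> KsExtraction:
        n = t.n_electrons
        RT_F = GAS_CONSTANT * t.temperature / (FARADAY * n)
        mask = t.delta_Ep > _IRREV_DEP_V / n
        if mask.sum() < 3:
            raise ValueError("irreversible_branch needs >= 3 rows with "
                             f"dEp > {1000 * _IRREV_DEP_V / n:.0f} mV")
        ln_nu = np.log(t.scan_rate[mask])
        e0 = t.formal_potential
        if e0 is None:
            e0 = float(np.mean(0.5 * (t.E_pa + t.E_pc)))
        fit_c = stats.linregress(ln_nu, t.E_pc[mask])
        fit_a = stats.linregress(ln_nu, t.E_pa[mask])
        if fit_c.slope >= 0 or fit_a.slope <= 0:
            raise ValueError("irreversible branches have the wrong slope signs")
        alpha_c = -RT_F / fit_c.slope
        alpha_a = 1.0 - RT_F / fit_a.slope
        alpha = float(np.clip(0.5 * (alpha_c + alpha_a), 1e-3, 1 - 1e-3))
        # ks from the scan rate at which each branch extrapolates to E0'
        ln_nu_c = (e0 - fit_c.intercept) / fit_c.slope
        ln_nu_a = (e0 - fit_a.intercept) / fit_a.slope
        ks_c = alpha * np.exp(ln_nu_c) / RT_F
        ks_a = (1.0 - alpha) * np.exp(ln_nu_a) / RT_F
        ks = float(np.sqrt(ks_c * ks_a))
        se = float(abs(ks_c - ks_a) / 2.0)
        return KsExtraction(ks=ks, ks_se=se, alpha=alpha,
                            temperature=t.temperature, method="irreversible_branch",
                            rows_used=int(mask.sum()))


def extract_ks(trumpet: TrumpetData, method: str = "working_curve",
               alpha: float = 0.5) -> KsExtraction:
    """Heterogeneous rate constant from one trumpet dataset (see
    :class:`LavironKsEstimator`)."""
    return LavironKsEstimator(method=method, alpha=alpha).fit(trumpet).result_


class ArrheniusEstimator(BaseEstimator):
    """Activation enthalpy from ln ks vs 1/T (kJ mol^-1 after ``fit``).

    The Arrhenius slope is identified with -dH_act/R directly; the small
    ``Ea = dH_act + RT`` correction is deliberately not applied because the
    activation entropy is treated as negligible throughout.
    """

    def fit(self, X, y=None):
        if y is None:
            df = pd.DataFrame(X)
            T = np.asarray(df.iloc[:, 0], dtype=float)
            ks = np.asarray(df.iloc[:, 1], dtype=float)
        else:
            T = np.asarray(X, dtype=float).reshape(-1)
            ks = np.asarray(y, dtype=float).reshape(-1)
        if T.size < 3:
            raise ValueError("need >= 3 temperatures")
        if T.max() - T.min() < 15.0:
            raise ValueError("temperature span must be >= 15 K")
        if np.any(ks <= 0):
            raise ValueError("rate constants must be > 0")
        fit = stats.linregress(1.0 / T, np.log(ks))
        self.slope_ = fit.slope
        self.activation_enthalpy_ = -GAS_CONSTANT * fit.slope / 1000.0
        self.activation_enthalpy_se_ = GAS_CONSTANT * fit.stderr / 1000.0
        self.prefactor_ln_ = fit.intercept
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.prefactor_ln_ + self.slope_ / T)


def arrhenius_activation(table) -> float:
    """Activation enthalpy (kJ mol^-1) from a (T, ks) table."""
    return ArrheniusEstimator().fit(table).activation_enthalpy_


def marcus_lambda(activation_enthalpy: float) -> float:
    """Marcus reorganization energy lambda = 4 * dH_act (units preserved)."""
    if activation_enthalpy < 0:
        raise ValueError("activation enthalpy must be >= 0")
    return 4.0 * activation_enthalpy


def prefactor_kT_over_h(T: float) -> float:
    """Tunneling pre-exponential nu0 = kT/h, s^-1."""
    if not T > 0:
        raise ValueError("temperature must be > 0 K")
    return BOLTZMANN * T / PLANCK


def tunneling_distance_interval(ks: float, activation_enthalpy: float, T: float,
                                nu0: Optional[float] = None, beta: float = 1.0,
                                r0_range: tuple = (0.0, 3.0),
                                d_sam: float = 19.0):
    """Tunneling-distance interval from ln ks = ln nu0 - beta(r - r0) - dH/(RT).

    Parameters
    ----------
    ks : float
        Standard rate constant, s^-1.
    activation_enthalpy : float
        dH_act in kJ mol^-1.
    nu0 : float, optional
        Pre-exponential, s^-1; defaults to kT/h at ``T``.
    beta : float
        Tunneling decay constant, A^-1 (~1 for alkanethiolate chains).
    r0_range : (float, float)
        Plausible range of the van der Waals contact distance r0, A.
    d_sam : float
        Through-monolayer tunneling distance, A.

    Returns a :class:`~pfvkit.types.TunnelingEstimate` whose
    ``surface_to_center_interval`` is ``r - d_sam`` over the r0 range,
    floored at zero (with a warning) when the geometry is unphysical.
    """
    if not ks > 0:
        raise ValueError("ks must be > 0")
    if not beta > 0:
        raise ValueError("beta must be > 0")
    r0_lo, r0_hi = float(r0_range[0]), float(r0_range[1])
    if not (0.0 <= r0_lo <= r0_hi <= 5.0):
        raise ValueError("r0_range must be an ordered interval within [0, 5] A")
    if nu0 is None:
        nu0 = prefactor_kT_over_h(T)
    dh_j = activation_enthalpy * 1000.0
    D = (np.log(nu0) - dh_j / (GAS_CONSTANT * T) - np.log(ks)) / beta
    if D < 0:
        raise ValueError("inferred tunneling distance is negative; "
                         "check ks, nu0 and the activation enthalpy")
    lo = D - d_sam + r0_lo
    hi = D - d_sam + r0_hi
    if lo < 0:
        warnings.warn("surface-to-center distance interval extends below zero "
                      "(redox center inside the monolayer); floored at 0",
                      DistanceWarning)
        lo, hi = max(lo, 0.0), max(hi, 0.0)
    return_interval = (float(lo), float(hi))
    from .types import TunnelingEstimate
    return TunnelingEstimate(nu0=float(nu0), beta=float(beta),
                             r0_range=(r0_lo, r0_hi), d_sam=float(d_sam),
                             total_distance_minus_r0=float(D),
                             surface_to_center_interval=return_interval)


def et_kinetics_summary(extractions: Sequence[KsExtraction]) -> ETKinetics:
    """Aggregate per-temperature ks extractions into Arrhenius + Marcus results.

    With >= 3 temperatures spanning >= 15 K the activation enthalpy and the
    reorganization energy are filled in; otherwise they stay ``None``.
    """
    usable = [e for e in extractions if e.ks is not None]
    alpha = usable[0].alpha if usable else 0.5
    dh = dh_se = lam = None
    if len(usable) >= 3:
        T = np.array([e.temperature for e in usable])
        ks = np.array([e.ks for e in usable])
        if T.max() - T.min() >= 15.0:
            est = ArrheniusEstimator().fit(T, ks)
            dh = est.activation_enthalpy_
            dh_se = est.activation_enthalpy_se_
            lam = marcus_lambda(max(dh, 0.0)) if dh >= 0 else None
            if dh < 0:
                warnings.warn("negative apparent activation enthalpy; "
                              "reorganization energy not evaluated", KineticsWarning)
    return ETKinetics(extractions=list(extractions), alpha=alpha,
                      activation_enthalpy=dh, activation_enthalpy_se=dh_se,
                      reorganization_energy=lam)
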