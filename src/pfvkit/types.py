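"""Domain containers for surface-confined voltammetry analysis.

All potentials are in volts, currents in amperes, charges in coulombs,
temperatures in kelvin, areas in cm^2 and surface coverages in mol cm^-2
unless a field name says otherwise.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import FARADAY, GAS_CONSTANT

__all__ = [
    "SimulationConfig",
    "Voltammogram",
    "GroundTruth",
    "PeakSet",
    "SurfaceCoverage",
    "RedoxThermo",
    "CompensationResult",
    "PhTitrationModel",
    "PhFitResult",
    "TrumpetData",
    "LavironWorkingCurve",
    "KsExtraction",
    "ETKinetics",
    "TunnelingEstimate",
]


@dataclass
class SimulationConfig:
    """Parameters of a surface-confined one-couple cyclic voltammetry simulation.

    The redox couple is adsorbed (diffusionless); interfacial kinetics follow
    the Butler-Volmer pair ``k_ox = ks*exp((1-alpha)*f*(E-E0'))`` and
    ``k_red = ks*exp(-alpha*f*(E-E0'))`` with ``f = F/(RT)``.

    Parameters
    ----------
    formal_potential : float
        Formal potential E0' of the adsorbed couple, V (vs the reference
        named in the output metadata).
    ks : float
        Standard heterogeneous electron-transfer rate constant, s^-1.
    alpha : float
        Transfer coefficient, dimensionless, in (0, 1).
    coverage_total : float
        Total surface coverage Gamma_T of redox sites, mol cm^-2.
    electrode_area : float
        Electrode area, cm^2.
    n_electrons : int
        Electrons exchanged per site.
    temperature : float
        Cell temperature, K.
    e_start, e_switch : float
        Start and switching potential of the sweep, V.
    scan_rate : float
        Sweep rate, V s^-1.
    double_layer_capacitance : float
        Specific double-layer capacitance, F cm^-2 (adds ``C*A*dE/dt``).
    noise_sd : float
        Standard deviation of additive Gaussian current noise, A.
    rng_seed : int
        Seed for the noise generator.
    potential_step : float
        Output potential resolution of the integration grid, V.
    """

    formal_potential: float
    ks: float
    coverage_total: float
    scan_rate: float
    e_start: float
    e_switch: float
    alpha: float = 0.5
    electrode_area: float = 0.02
    n_electrons: int = 1
    temperature: float = 298.15
    double_layer_capacitance: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    potential_step: float = 1e-4

    def __post_init__(self) -> None:
        if not self.scan_rate > 0:
            raise ValueError("scan_rate must be > 0")
        if self.e_start == self.e_switch:
            raise ValueError("e_start and e_switch must differ")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.ks < 0:
            raise ValueError("ks must be >= 0")
        if not self.coverage_total > 0:
            raise ValueError("coverage_total must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if not self.electrode_area > 0:
            raise ValueError("electrode_area must be > 0")
        if int(self.n_electrons) != self.n_electrons or self.n_electrons < 1:
            raise ValueError("n_electrons must be a positive integer")
        if not self.potential_step > 0:
            raise ValueError("potential_step must be > 0")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class Voltammogram:
    """A cyclic voltammogram: potential/current series plus acquisition metadata."""

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    temperature: float
    electrode_area: Optional[float] = None
    n_electrons: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape or self.potential.size < 2:
            raise ValueError("potential and current must be equal-length series of >= 2 points")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if not self.scan_rate > 0:
            raise ValueError("scan_rate must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"potential_V": self.potential, "current_A": self.current})

    def __len__(self) -> int:
        return self.potential.size


@dataclass
class GroundTruth:
    """Simulation ground truth stored alongside every synthetic voltammogram.

    ``reversible_peak_current`` and ``reversible_fwhm`` are the closed-form
    ideal (Nernstian) surface-wave values ``n^2 F^2 v A Gamma_T / (4RT)`` and
    ``3.53 RT/(nF)`` implied by the configuration.
    """

    config: SimulationConfig
    reversible_peak_current: float
    reversible_fwhm: float
    window_warning: bool = False

    @classmethod
    def from_config(cls, config: SimulationConfig, window_warning: bool = False) -> "GroundTruth":
        n, T = config.n_electrons, config.temperature
        ip = (n * FARADAY) ** 2 * config.scan_rate * config.electrode_area \
            * config.coverage_total / (4.0 * GAS_CONSTANT * T)
        fwhm = 3.53 * GAS_CONSTANT * T / (n * FARADAY)
        return cls(config=config, reversible_peak_current=ip,
                   reversible_fwhm=fwhm, window_warning=window_warning)


@dataclass
class PeakSet:
    """Anodic/cathodic peak parameters extracted from one voltammogram.

    Currents are baseline-corrected and signed (anodic positive); charges are
    magnitudes of the baseline-corrected peak areas divided by the scan rate.
    """

    E_pa: float
    E_pc: float
    i_pa: float
    i_pc: float
    Q_a: float
    Q_c: float
    baseline_anodic: tuple
    baseline_cathodic: tuple

    def __post_init__(self) -> None:
        if self.Q_a < 0 or self.Q_c < 0:
            raise ValueError("peak charges must be >= 0")

    @property
    def delta_Ep(self) -> float:
        return self.E_pa - self.E_pc

    @property
    def midpoint(self) -> float:
        """Midpoint (formal) potential: semi-sum of the peak potentials."""
        return 0.5 * (self.E_pa + self.E_pc)


@dataclass
class SurfaceCoverage:
    """Electroactive surface coverage from integrated peak charge."""

    gamma0: float
    Q_tot: float
    area: float
    n_electrons: int
    scan_rate: float

    def __post_init__(self) -> None:
        if not self.gamma0 > 0:
            raise ValueError("gamma0 must be > 0")


@dataclass
class RedoxThermo:
    """Reduction thermodynamics from the temperature dependence of E0'.

    entropy_rc in J mol^-1 K^-1, enthalpy_rc and gibbs_rc in kJ mol^-1;
    gibbs_rc refers to T_ref.
    """

    E_ref: float
    T_ref: float
    n: int
    dE_dT: float
    dE_dT_se: float
    entropy_rc: float
    entropy_rc_se: float
    enthalpy_rc: float
    enthalpy_rc_se: float
    gibbs_rc: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        g_id = self.enthalpy_rc - self.T_ref * self.entropy_rc / 1000.0
        if abs(self.gibbs_rc - g_id) > 1e-6:
            raise ValueError("gibbs_rc must equal enthalpy_rc - T_ref*entropy_rc")


@dataclass
class CompensationResult:
    """Enthalpy-entropy compensation regression across conditions."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    studentized_residuals: np.ndarray
    outlier_mask: np.ndarray
    refit_slope: Optional[float] = None
    refit_intercept: Optional[float] = None

    def __post_init__(self) -> None:
        self.studentized_residuals = np.asarray(self.studentized_residuals, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.outlier_mask.sum() >= self.outlier_mask.size:
            raise ValueError("cannot flag every point as an outlier")


@dataclass
class PhTitrationModel:
    """E0'(pH) model with up to three coupled acid-base equilibria.

    E0'(pH) = E_lowpH + c * sum_i log10((Ka_red,i + [H+]) / (Ka_ox,i + [H+]))

    with ``c`` the Nernst coefficient (V per decade) and ``[H+] = 10^-pH``.
    Each equilibrium couples a pKa of the oxidized protein to a higher pKa of
    the reduced protein (reduction-induced proton uptake), so E0' decreases
    with pH and equals ``E_lowpH`` in the acid limit.
    """

    E_lowpH: float
    equilibria: Sequence[tuple]
    nernst_coefficient: float = 0.059
    temperature: float = 293.15

    def __post_init__(self) -> None:
        eq = [(float(a), float(b)) for a, b in self.equilibria]
        if not 1 <= len(eq) <= 3:
            raise ValueError("between 1 and 3 acid-base equilibria are supported")
        for pka_ox, pka_red in eq:
            if not pka_red > pka_ox:
                raise ValueError("each pair requires pKa_red > pKa_ox")
            if not (2.0 <= pka_ox <= 13.0 and 2.0 <= pka_red <= 13.0):
                raise ValueError("pKa values must lie in [2, 13]")
        if not self.nernst_coefficient > 0:
            raise ValueError("nernst_coefficient must be > 0")
        self.equilibria = eq

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)

    @property
    def total_span(self) -> float:
        """E0'(acid limit) - E0'(alkaline limit) = c * sum(pKa_red - pKa_ox)."""
        return self.nernst_coefficient * sum(r - o for o, r in self.equilibria)


@dataclass
class PhFitResult:
    """Outcome of the multi-start nonlinear fit of the pH titration model."""

    model: PhTitrationModel
    stderr: dict
    residual_rms: float
    n_equilibria: int
    n_points: int
    objective: float
    multistart_objectives: np.ndarray
    at_bounds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.multistart_objectives = np.asarray(self.multistart_objectives, dtype=float)
        if not np.isfinite(self.residual_rms):
            raise ValueError("residual RMS must be finite")
        finite = self.multistart_objectives[np.isfinite(self.multistart_objectives)]
        if finite.size and self.objective > finite.min() + 1e-12:
            raise ValueError("best objective must not exceed any multi-start objective")

    @property
    def aicc(self) -> float:
        n = self.n_points
        k = 2 + 2 * self.n_equilibria  # E_lowpH + pairs + sigma
        if n - k - 1 <= 0:
            return np.inf
        rss = max(self.objective, 1e-300)
        return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class TrumpetData:
    """Peak potentials vs scan rate ('trumpet plot') at one temperature."""

    scan_rate: np.ndarray
    E_pa: np.ndarray
    E_pc: np.ndarray
    temperature: float
    formal_potential: Optional[float] = None
    n_electrons: int = 1
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.scan_rate = np.asarray(self.scan_rate, dtype=float)
        self.E_pa = np.asarray(self.E_pa, dtype=float)
        self.E_pc = np.asarray(self.E_pc, dtype=float)
        if self.scan_rate.size < 4:
            raise ValueError("a trumpet dataset needs >= 4 scan rates")
        if self.scan_rate.size != self.E_pa.size or self.scan_rate.size != self.E_pc.size:
            raise ValueError("scan_rate, E_pa, E_pc must have equal length")
        if np.any(self.scan_rate <= 0):
            raise ValueError("scan rates must be > 0")
        if np.unique(self.scan_rate).size != self.scan_rate.size:
            raise ValueError("scan rates must be distinct")

    @property
    def delta_Ep(self) -> np.ndarray:
        return self.E_pa - self.E_pc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"scan_rate_V_per_s": self.scan_rate,
                             "E_pa_V": self.E_pa, "E_pc_V": self.E_pc})


@dataclass
class LavironWorkingCurve:
    """Dimensionless working curve for the Laviron trumpet-plot method.

    Maps ``m_inv = (F/RT) * (nu/ks)`` to the dimensionless peak separation
    ``dEp * nF/(RT)`` for a given transfer coefficient; strictly increasing
    and -> 0 in the reversible limit.
    """

    alpha: float
    m_inv: np.ndarray
    delta_ep_dimless: np.ndarray
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.m_inv = np.asarray(self.m_inv, dtype=float)
        self.delta_ep_dimless = np.asarray(self.delta_ep_dimless, dtype=float)
        if np.any(np.diff(self.m_inv) <= 0):
            raise ValueError("m_inv grid must be strictly increasing")
        if np.any(np.diff(self.delta_ep_dimless) <= 0):
            raise ValueError("working curve must be strictly increasing")

    def invert(self, delta_ep_dimless):
        """m_inv at a given dimensionless peak separation (log-log interpolation)."""
        d = np.atleast_1d(np.asarray(delta_ep_dimless, dtype=float))
        lo, hi = self.delta_ep_dimless[0], self.delta_ep_dimless[-1]
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError("peak separation outside the working-curve range")
        out = np.exp(np.interp(np.log(d), np.log(self.delta_ep_dimless), np.log(self.m_inv)))
        return out if np.ndim(delta_ep_dimless) else float(out[0])


@dataclass
class KsExtraction:
    """Heterogeneous ET rate constant extracted from one trumpet dataset."""

    ks: Optional[float]
    ks_se: Optional[float]
    alpha: float
    temperature: float
    method: str
    lower_bound_only: bool = False
    ks_lower_bound: Optional[float] = None
    per_row_ks: Optional[np.ndarray] = None
    rows_used: int = 0

    def __post_init__(self) -> None:
        if self.ks is not None and not self.ks > 0:
            raise ValueError("ks must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ETKinetics:
    """Electron-transfer kinetics summary across temperatures.

    activation_enthalpy and reorganization_energy in kJ mol^-1;
    the Marcus relation lambda = 4*dH_act holds by construction.
    """

    extractions: list
    alpha: float
    activation_enthalpy: Optional[float] = None
    activation_enthalpy_se: Optional[float] = None
    reorganization_energy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.activation_enthalpy is not None and self.reorganization_energy is not None:
            if abs(self.reorganization_energy - 4.0 * self.activation_enthalpy) > 1e-9:
                raise ValueError("reorganization_energy must equal 4*activation_enthalpy")


@dataclass
class TunnelingEstimate:
    """Tunneling-distance bookkeeping from ln ks = ln nu0 - beta*(r - r0) - dH/(RT)."""

    nu0: float
    beta: float
    r0_range: tuple
    d_sam: float
    total_distance_minus_r0: float
    surface_to_center_interval: tuple

    def __post_init__(self) -> None:
        r0_lo, r0_hi = self.r0_range
        lo, hi = self.surface_to_center_interval
        if r0_lo < 0 or r0_hi < r0_lo:
            raise ValueError("r0_range must be an ordered non-negative interval")
        if lo < 0 or hi < lo:
            raise ValueError("surface_to_center_interval must be ordered and >= 0")
        if self.total_distance_minus_r0 < 0:
            raise ValueError("tunneling distance must be >= 0")
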