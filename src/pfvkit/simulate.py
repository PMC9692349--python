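"""Synthetic data generation for the full analysis chain.

The central piece is a simulator of cyclic voltammograms of an adsorbed
(diffusionless) one-couple redox film with Butler-Volmer interfacial
kinetics — the regime treated by Laviron's model.  The oxidized fraction
``x`` of the film obeys

    dx/dt = k_ox(E) * (1 - x) - k_red(E) * x
    k_ox  = ks * exp((1 - alpha) * f * (E - E0')),   f = F/(RT)
    k_red = ks * exp(-alpha * f * (E - E0'))

under a triangular potential program, and the faradaic current is
``i = n F A Gamma_T dx/dt`` (IUPAC convention: anodic current positive).
The equation is stiff in the reversible limit (large ``ks``), so the
integrator is exponential: over each potential step the rates are frozen at
the midpoint potential and the update

    x_{k+1} = x_inf + (x_k - x_inf) * exp(-(k_ox + k_red) * dt)

is exact for the frozen-rate problem and unconditionally stable.  Internal
sub-stepping keeps the rate variation per update below 0.1 mV regardless of
the requested output resolution.

The module also generates the derived datasets the downstream stages
consume: linear E0'(T) series, E0'(pH) titration curves, and trumpet-plot
(peak potential vs scan rate) tables, each with known ground truth.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import FARADAY, GAS_CONSTANT
from .errors import StiffnessError
from .types import GroundTruth, PhTitrationModel, SimulationConfig, TrumpetData, Voltammogram

__all__ = [
    "simulate_surface_cv",
    "generate_temperature_series",
    "generate_ph_series",
    "generate_trumpet_series",
]

_MAX_EXP = 700.0  # exp() overflow guard
_SUBSTEP_V = 1e-4  # max potential change per exponential update, V


def _segment_grid(e_from: float, e_to: float, step: float) -> np.ndarray:
    n = max(2, int(round(abs(e_to - e_from) / step)) + 1)
    return np.linspace(e_from, e_to, n)


def _propagate(e_nodes: np.ndarray, x0: float, cfg: SimulationConfig) -> np.ndarray:
    """Integrate the oxidized fraction along one monotone sweep segment."""
    f = FARADAY * cfg.n_electrons / (GAS_CONSTANT * cfg.temperature)
    step = abs(e_nodes[1] - e_nodes[0])
    n_sub = max(1, int(math.ceil(step / _SUBSTEP_V)))
    dt_sub = step / (cfg.scan_rate * n_sub)

    if cfg.ks == 0.0:
        return np.full(e_nodes.size, x0)

    # midpoint potentials of every sub-step, vectorized
    direction = np.sign(e_nodes[-1] - e_nodes[0])
    sub_offsets = (np.arange(n_sub) + 0.5) * (step / n_sub) * direction
    e_mid = (e_nodes[:-1, None] + sub_offsets[None, :]).ravel()

    eta = f * (e_mid - cfg.formal_potential)
    k_ox = cfg.ks * np.exp(np.clip((1.0 - cfg.alpha) * eta, -_MAX_EXP, _MAX_EXP))
    k_red = cfg.ks * np.exp(np.clip(-cfg.alpha * eta, -_MAX_EXP, _MAX_EXP))
    k_sum = k_ox + k_red
    decay = np.exp(-k_sum * dt_sub)
    x_inf = k_ox / k_sum

    x = np.empty(e_nodes.size)
    x[0] = xk = x0
    xi_l = x_inf.tolist()
    dc_l = decay.tolist()
    idx = 0
    for node in range(1, e_nodes.size):
        for _ in range(n_sub):
            xi = xi_l[idx]
            xk = xi + (xk - xi) * dc_l[idx]
            idx += 1
        x[node] = xk
    return x


def simulate_surface_cv(config: SimulationConfig):
    """Simulate one full cyclic voltammogram of the adsorbed couple.

    Returns
    -------
    (Voltammogram, GroundTruth)
        Both sweep segments concatenated; the current is the sum of the
        faradaic, capacitive and (seeded) Gaussian noise components.
        ``metadata['segment_split_index']`` marks the first index of the
        return sweep.
    """
    cfg = config
    seg1 = _segment_grid(cfg.e_start, cfg.e_switch, cfg.potential_step)
    step_back = abs(seg1[1] - seg1[0])
    seg2_full = _segment_grid(cfg.e_switch, cfg.e_start, step_back)
    seg2 = seg2_full[1:]  # e_switch appears once

    f = FARADAY * cfg.n_electrons / (GAS_CONSTANT * cfg.temperature)
    # Nernst-equilibrium oxidized fraction at the start potential
    x0 = 1.0 / (1.0 + math.exp(np.clip(-f * (cfg.e_start - cfg.formal_potential),
                                       -_MAX_EXP, _MAX_EXP)))

    x1 = _propagate(seg1, x0, cfg)
    x2_full = _propagate(seg2_full, x1[-1], cfg)

    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2_full))):
        raise StiffnessError(
            "integration produced non-finite oxidized fractions; "
            "reduce potential_step")

    scale = cfg.n_electrons * FARADAY * cfg.electrode_area * cfg.coverage_total
    dt1 = abs(seg1[1] - seg1[0]) / cfg.scan_rate
    dt2 = abs(seg2_full[1] - seg2_full[0]) / cfg.scan_rate
    i1 = scale * np.gradient(x1, dt1)
    i2 = scale * np.gradient(x2_full, dt2)[1:]

    sgn1 = np.sign(cfg.e_switch - cfg.e_start)
    i_cap = cfg.double_layer_capacitance * cfg.electrode_area * cfg.scan_rate
    i1 = i1 + sgn1 * i_cap
    i2 = i2 - sgn1 * i_cap

    potential = np.concatenate([seg1, seg2])
    current = np.concatenate([i1, i2])
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.rng_seed)
        current = current + rng.normal(0.0, cfg.noise_sd, current.size)

    lo, hi = min(cfg.e_start, cfg.e_switch), max(cfg.e_start, cfg.e_switch)
    window_warning = not (lo <= cfg.formal_potential - 0.150
                          and cfg.formal_potential + 0.150 <= hi)

    truth = GroundTruth.from_config(cfg, window_warning=window_warning)
    vg = Voltammogram(
        potential=potential,
        current=current,
        scan_rate=cfg.scan_rate,
        temperature=cfg.temperature,
        electrode_area=cfg.electrode_area,
        n_electrons=cfg.n_electrons,
        metadata={
            "reference": "SHE",
            "segment_split_index": seg1.size,
            "formal_potential_true_V": cfg.formal_potential,
            "ks_true_per_s": cfg.ks,
            "alpha_true": cfg.alpha,
            "coverage_true_mol_per_cm2": cfg.coverage_total,
        },
    )
    return vg, truth


def generate_temperature_series(E_ref: float, T_ref: float, entropy: float,
                                n: int, T_grid: Sequence[float],
                                noise_sd: float = 0.0,
                                seed: int = 0) -> pd.DataFrame:
    """Linear E0'(T) series: E0'(T) = E_ref + (entropy/(nF)) * (T - T_ref) + noise.

    ``entropy`` is the reduction entropy in J mol^-1 K^-1, so the slope is
    ``entropy/(nF)`` V/K.  Returns a DataFrame with columns
    ``temperature_K`` and ``E_V``; ground truth in ``df.attrs``.
    """
    T = np.asarray(list(T_grid), dtype=float)
    if T.size == 0:
        raise ValueError("temperature grid is empty")
    if np.any(T < 278.0) or np.any(T > 318.0):
        raise ValueError("temperature grid must lie within 278-318 K")
    E = E_ref + entropy / (n * FARADAY) * (T - T_ref)
    if noise_sd > 0:
        E = E + np.random.default_rng(seed).normal(0.0, noise_sd, T.size)
    df = pd.DataFrame({"temperature_K": T, "E_V": E})
    df.attrs["ground_truth"] = {"E_ref": E_ref, "T_ref": T_ref,
                                "entropy": entropy, "n": n,
                                "noise_sd": noise_sd, "seed": seed}
    return df


def generate_ph_series(model: PhTitrationModel, pH_grid: Sequence[float],
                       T: float = 293.15, noise_sd: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """E0'(pH) series from the acid-base titration model plus Gaussian noise."""
    from .titration import eval_ph_model

    pH = np.asarray(list(pH_grid), dtype=float)
    if pH.size == 0:
        raise ValueError("pH grid is empty")
    if np.any(pH < 0.0) or np.any(pH > 14.0):
        raise ValueError("pH values must lie in [0, 14]")
    E = eval_ph_model(model, pH)
    if noise_sd > 0:
        E = E + np.random.default_rng(seed).normal(0.0, noise_sd, pH.size)
    df = pd.DataFrame({"pH": pH, "E_V": E})
    df.attrs["ground_truth"] = {"model": model, "temperature_K": T,
                                "noise_sd": noise_sd, "seed": seed}
    return df


def generate_trumpet_series(config: SimulationConfig,
                            scan_rates: Sequence[float],
                            noise_fraction_of_peak: Optional[float] = None) -> TrumpetData:
    """Simulate CVs over a set of scan rates and reduce them to a trumpet table.

    Each scan rate gets its own simulation (seed derived from
    ``config.rng_seed``) followed by peak picking.  If
    ``noise_fraction_of_peak`` is given, the current noise of each CV is that
    fraction of the ideal reversible-limit peak current at its scan rate,
    overriding ``config.noise_sd``.
    """
    from .processing import find_peaks

    rates = np.asarray(list(scan_rates), dtype=float)
    if np.any(rates <= 0):
        raise ValueError("scan rates must be > 0")

    e_pa, e_pc = [], []
    for i, nu in enumerate(rates):
        cfg = config.replace(scan_rate=float(nu),
                             rng_seed=int(config.rng_seed) + 1000 * i)
        if noise_fraction_of_peak is not None:
            ip_rev = (cfg.n_electrons * FARADAY) ** 2 * nu * cfg.electrode_area \
                * cfg.coverage_total / (4.0 * GAS_CONSTANT * cfg.temperature)
            cfg = cfg.replace(noise_sd=noise_fraction_of_peak * ip_rev)
        vg, _ = simulate_surface_cv(cfg)
        peaks = find_peaks(vg)
        e_pa.append(peaks.E_pa)
        e_pc.append(peaks.E_pc)

    return TrumpetData(
        scan_rate=rates, E_pa=np.array(e_pa), E_pc=np.array(e_pc),
        temperature=config.temperature,
        formal_potential=config.formal_potential,
        n_electrons=config.n_electrons,
        ground_truth={"ks": config.ks, "alpha": config.alpha},
    )
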