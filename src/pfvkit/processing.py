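"""Reduction of a cyclic voltammogram to peak parameters and derived quantities.

A CV of an adsorbed couple is split into its two monotone sweep segments,
each segment gets a linear baseline fitted through its flanking windows, and
the baseline-corrected extrema give the anodic/cathodic peak potentials and
currents.  The formal potential is the semi-sum of the two peak potentials;
integrated, baseline-corrected peak charge divided by ``nFA`` gives the
electroactive surface coverage (``int i(E) dE = nu * n F A Gamma_0``).
"""
from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.signal import savgol_filter

from .constants import FARADAY, GAS_CONSTANT, SCE_TO_SHE_VOLT
from .errors import BaselineWarning, NoPeakError, SegmentationError
from .types import PeakSet, SurfaceCoverage, Voltammogram

__all__ = [
    "split_segments",
    "baseline_correct",
    "find_peaks",
    "surface_coverage",
    "electrode_area_randles_sevcik",
    "convert_reference",
    "measure_fwhm",
]


def split_segments(vg: Voltammogram) -> Tuple[slice, slice]:
    """Slices of the anodic (potential increasing) and cathodic sweep segments."""
    E = vg.potential
    split = vg.metadata.get("segment_split_index")
    if split is None:
        dE = np.diff(E)
        sign_changes = np.flatnonzero(np.sign(dE[1:]) != np.sign(dE[:-1]))
        if sign_changes.size == 0:
            raise SegmentationError("potential program has a single sweep direction")
        if sign_changes.size > 1:
            raise SegmentationError("potential program has more than two sweep segments")
        split = int(sign_changes[0]) + 2
    split = int(split)
    seg_a, seg_b = slice(0, split), slice(split, len(E))
    for seg in (seg_a, seg_b):
        d = np.diff(E[seg])
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise SegmentationError("sweep segment is not strictly monotone in potential")
    first_increasing = E[1] > E[0]
    return (seg_a, seg_b) if first_increasing else (seg_b, seg_a)


def _flank_indices(n: int, flank_fraction: float) -> Tuple[np.ndarray, np.ndarray]:
    w = max(3, int(round(flank_fraction * n)))
    return np.arange(w), np.arange(n - w, n)


def baseline_correct(vg: Voltammogram, segment: str = "cathodic",
                     flank_fraction: float = 0.1):
    """Subtract a linear baseline fitted through the two flanks of a segment.

    Returns ``(corrected_current, (slope, intercept), segment_slice)``.
    A warning is raised when the segment's extremum lies inside a flank
    window (the baseline then eats part of the peak).
    """
    if not 0.0 < flank_fraction <= 0.25:
        raise ValueError("flank_fraction must lie in (0, 0.25]")
    anodic, cathodic = split_segments(vg)
    sl = anodic if segment == "anodic" else cathodic
    if segment not in ("anodic", "cathodic"):
        raise ValueError("segment must be 'anodic' or 'cathodic'")
    E = vg.potential[sl]
    i = vg.current[sl]
    if E.size < 8:
        raise NoPeakError("sweep segment too short to hold a peak between "
                          "baseline flanks")
    left, right = _flank_indices(E.size, flank_fraction)
    idx = np.concatenate([left, right])
    slope, intercept = np.polyfit(E[idx], i[idx], 1)
    corrected = i - (slope * E + intercept)
    ext = int(np.argmax(corrected)) if segment == "anodic" else int(np.argmin(corrected))
    if ext <= left[-1] or ext >= right[0]:
        warnings.warn(
            "segment extremum lies inside a baseline flank window; "
            "consider a smaller flank_fraction", BaselineWarning)
    return corrected, (float(slope), float(intercept)), sl


def _noise_sigma(corrected: np.ndarray, flank_fraction: float) -> float:
    left, right = _flank_indices(corrected.size, flank_fraction)
    res = np.concatenate([corrected[left], corrected[right]])
    return 1.4826 * float(np.median(np.abs(res - np.median(res))))


def _refine_peak(E: np.ndarray, y: np.ndarray, idx: int,
                 top_fraction: float = 0.9) -> Tuple[float, float]:
    """Vertex of a least-squares parabola through the contiguous peak top."""
    peak = y[idx]
    thr = top_fraction * peak
    lo = idx
    while lo > 0 and y[lo - 1] >= thr:
        lo -= 1
    hi = idx
    while hi < y.size - 1 and y[hi + 1] >= thr:
        hi += 1
    lo, hi = max(0, min(lo, idx - 1)), min(y.size - 1, max(hi, idx + 1))
    Ew, yw = E[lo:hi + 1], y[lo:hi + 1]
    c = np.polyfit(Ew - E[idx], yw, 2)
    if c[0] >= 0:  # not concave: keep the grid point
        return float(E[idx]), float(peak)
    e_vertex = -c[1] / (2.0 * c[0])
    i_vertex = np.polyval(c, e_vertex)
    e_vertex += E[idx]
    lo_E, hi_E = min(Ew[0], Ew[-1]), max(Ew[0], Ew[-1])
    if not lo_E <= e_vertex <= hi_E:  # refinement escaped the window
        return float(E[idx]), float(peak)
    return float(e_vertex), float(i_vertex)


def _peak_charge(E: np.ndarray, corrected: np.ndarray, idx: int,
                 scan_rate: float) -> float:
    """|integral of corrected current dE| / nu over the peak support.

    The support runs between the zero-crossings of the corrected current
    flanking the peak, falling back to a +-150 mV window if a side never
    crosses zero.
    """
    y = corrected
    sign = np.sign(y[idx])
    lo = idx
    while lo > 0 and y[lo - 1] * sign > 0 and abs(E[lo - 1] - E[idx]) <= 0.150:
        lo -= 1
    hi = idx
    while hi < y.size - 1 and y[hi + 1] * sign > 0 and abs(E[hi + 1] - E[idx]) <= 0.150:
        hi += 1
    q = np.trapezoid(y[lo:hi + 1], E[lo:hi + 1])
    return abs(q) / scan_rate


def _segment_peak(vg: Voltammogram, segment: str, flank_fraction: float,
                  top_fraction: float):
    corrected, coeffs, sl = baseline_correct(vg, segment, flank_fraction)
    E = vg.potential[sl]
    sigma = _noise_sigma(corrected, flank_fraction)
    signed = corrected if segment == "anodic" else -corrected

    work = signed
    if sigma > 0 and np.max(signed) > 0 and sigma > 0.002 * np.max(signed):
        win = min(signed.size - (signed.size + 1) % 2,
                  max(5, 2 * (signed.size // 40) + 1))
        work = savgol_filter(signed, win, 2)

    idx = int(np.argmax(work))
    peak_height = work[idx]
    floor = max(3.0 * sigma, 1e-18)
    if E.size < 5 or peak_height < floor:
        raise NoPeakError(f"no {segment} peak above the noise floor "
                          f"(height {peak_height:.3g} A vs floor {floor:.3g} A)")
    e_p, i_p = _refine_peak(E, work, idx, top_fraction)
    q = _peak_charge(E, signed, idx, vg.scan_rate)
    i_signed = i_p if segment == "anodic" else -i_p
    return e_p, i_signed, q, coeffs


def find_peaks(vg: Voltammogram, flank_fraction: float = 0.1,
               top_fraction: float = 0.9) -> PeakSet:
    """Locate the anodic and cathodic peaks of a cyclic voltammogram.

    Each sweep segment is baseline-corrected; the peak potential is refined
    below the grid resolution by a parabola fitted to the top of the peak
    (Savitzky-Golay pre-smoothing kicks in when the flank noise is
    significant relative to the peak).  Peak charges come from trapezoidal
    integration of the corrected current between its zero-crossings around
    the peak, divided by the scan rate.

    Raises
    ------
    NoPeakError
        If a segment has no extremum at least 3 flank-MADs above the noise.
    """
    E_pa, i_pa, Q_a, base_a = _segment_peak(vg, "anodic", flank_fraction, top_fraction)
    E_pc, i_pc, Q_c, base_c = _segment_peak(vg, "cathodic", flank_fraction, top_fraction)
    return PeakSet(E_pa=E_pa, E_pc=E_pc, i_pa=i_pa, i_pc=i_pc,
                   Q_a=Q_a, Q_c=Q_c,
                   baseline_anodic=base_a, baseline_cathodic=base_c)


def surface_coverage(peaks: PeakSet, vg: Voltammogram) -> SurfaceCoverage:
    """Electroactive coverage Gamma_0 = Q_c / (n F A) from the cathodic charge."""
    if vg.electrode_area is None or not vg.electrode_area > 0:
        raise ValueError("voltammogram needs a positive electrode_area")
    n = vg.n_electrons
    gamma0 = peaks.Q_c / (n * FARADAY * vg.electrode_area)
    return SurfaceCoverage(gamma0=gamma0, Q_tot=peaks.Q_c,
                           area=vg.electrode_area, n_electrons=n,
                           scan_rate=vg.scan_rate)


def electrode_area_randles_sevcik(peak_current: float, concentration: float,
                                  diffusion_coefficient: float,
                                  scan_rate: float, n: int = 1,
                                  T: float = 298.15) -> float:
    """Electrode area from the Randles-Sevcik peak current of a reversible,
    diffusion-controlled couple:

        i_p = 0.4463 n F A C sqrt(n F nu D / (R T))

    concentration in mol cm^-3, D in cm^2 s^-1; returns cm^2.
    """
    for name, v in [("peak_current", peak_current), ("concentration", concentration),
                    ("diffusion_coefficient", diffusion_coefficient),
                    ("scan_rate", scan_rate), ("n", n), ("T", T)]:
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    root = np.sqrt(n * FARADAY * scan_rate * diffusion_coefficient / (GAS_CONSTANT * T))
    return peak_current / (0.4463 * n * FARADAY * concentration * root)


def convert_reference(E: float, from_ref: str, to_ref: str, T: float = 298.15):
    """Convert a potential between the SCE and SHE scales (fixed +0.2412 V offset)."""
    offsets = {"SHE": 0.0, "SCE": SCE_TO_SHE_VOLT}
    for name in (from_ref, to_ref):
        if name not in offsets:
            raise ValueError(f"unsupported reference electrode: {name!r}")
    return E + offsets[from_ref] - offsets[to_ref]


def measure_fwhm(E: np.ndarray, current: np.ndarray) -> float:
    """Full width at half maximum of a single baseline-free peak, by linear
    interpolation of the half-height crossings."""
    E = np.asarray(E, dtype=float)
    y = np.asarray(current, dtype=float)
    y = y if abs(y.max()) >= abs(y.min()) else -y
    idx = int(np.argmax(y))
    half = y[idx] / 2.0
    left = right = None
    for k in range(idx, 0, -1):
        if y[k - 1] <= half <= y[k]:
            left = E[k - 1] + (E[k] - E[k - 1]) * (half - y[k - 1]) / (y[k] - y[k - 1])
            break
    for k in range(idx, y.size - 1):
        if y[k + 1] <= half <= y[k]:
            right = E[k] + (E[k + 1] - E[k]) * (half - y[k]) / (y[k + 1] - y[k])
            break
    if left is None or right is None:
        raise ValueError("half-height crossings not bracketed by the data")
    return abs(right - left)
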