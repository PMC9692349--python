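"""Simulator: closed-form limits, conservation laws, convergence, noise contract."""
import numpy as np
import pytest

import pfvkit as pk
from pfvkit.constants import FARADAY


def test_reversible_limit_peaks_coincide(reversible_cv):
    """Nernstian surface couple: anodic and cathodic peaks at E0', dEp ~ 0."""
    vg, truth = reversible_cv
    peaks = pk.find_peaks(vg)
    assert abs(peaks.delta_Ep) < 1e-3
    assert abs(peaks.midpoint - 0.0) < 1e-3


def test_reversible_limit_fwhm_and_peak_current(reversible_cv):
    """Ideal surface wave: FWHM = 3.53 RT/F, i_p = F^2 v A Gamma / (4RT)."""
    vg, truth = reversible_cv
    corr, _, sl = pk.baseline_correct(vg, "anodic")
    fwhm = pk.measure_fwhm(vg.potential[sl], corr)
    assert abs(fwhm - truth.reversible_fwhm) < 0.5e-3
    peaks = pk.find_peaks(vg)
    assert peaks.i_pa == pytest.approx(truth.reversible_peak_current, rel=5e-3)
    assert abs(peaks.i_pc) == pytest.approx(truth.reversible_peak_current, rel=5e-3)


def test_charge_conservation(base_config):
    """With no noise or capacitance, the faradaic charge of a full sweep
    equals n F A Gamma_T within 0.1% (window widened to capture the tails)."""
    cfg = base_config.replace(e_start=0.097 - 0.4, e_switch=0.097 + 0.4)
    vg, _ = pk.simulate_surface_cv(cfg)
    an, ca = pk.split_segments(vg)
    q_expected = cfg.n_electrons * FARADAY * cfg.electrode_area * cfg.coverage_total
    for seg in (an, ca):
        q = abs(np.trapezoid(vg.current[seg], vg.potential[seg])) / cfg.scan_rate
        assert q == pytest.approx(q_expected, rel=1e-3)


def test_peak_current_linear_in_scan_rate(base_config):
    """Diffusionless signature: i_p proportional to scan rate, R^2 > 0.999
    (fast-kinetics regime, where peak height is not kinetically broadened)."""
    rates = np.array([0.02, 0.05, 0.1, 0.2, 0.4])
    ip = []
    for nu in rates:
        vg, _ = pk.simulate_surface_cv(base_config.replace(
            ks=1e4, scan_rate=float(nu),
            e_start=0.097 - 0.35, e_switch=0.097 + 0.35))
        ip.append(pk.find_peaks(vg).i_pa)
    ip = np.array(ip)
    coef = np.polyfit(rates, ip, 1)
    r2 = 1 - np.sum((ip - np.polyval(coef, rates)) ** 2) / np.sum((ip - ip.mean()) ** 2)
    assert r2 > 0.999
    assert abs(coef[1]) < 0.02 * ip.max()  # intercept ~ 0


def test_symmetric_alpha_symmetric_peak_currents(quasireversible_cv):
    vg, _ = quasireversible_cv
    peaks = pk.find_peaks(vg)
    assert abs(peaks.i_pa) == pytest.approx(abs(peaks.i_pc), rel=0.01)
    assert peaks.Q_a == pytest.approx(peaks.Q_c, rel=0.01)


def test_step_self_convergence(base_config):
    """Halving the output step below 0.1 mV moves Ep by < 0.2 mV."""
    p1 = pk.find_peaks(pk.simulate_surface_cv(base_config)[0])
    p2 = pk.find_peaks(pk.simulate_surface_cv(
        base_config.replace(potential_step=5e-5))[0])
    assert abs(p1.E_pa - p2.E_pa) < 0.2e-3
    assert abs(p1.E_pc - p2.E_pc) < 0.2e-3


def test_noise_reproducible_and_deterministic(base_config):
    cfg = base_config.replace(noise_sd=1e-9, rng_seed=11)
    v1, _ = pk.simulate_surface_cv(cfg)
    v2, _ = pk.simulate_surface_cv(cfg)
    np.testing.assert_array_equal(v1.current, v2.current)
    v3, _ = pk.simulate_surface_cv(cfg.replace(rng_seed=12))
    assert not np.array_equal(v1.current, v3.current)
    # noiseless output is fully deterministic
    a, _ = pk.simulate_surface_cv(base_config)
    b, _ = pk.simulate_surface_cv(base_config)
    np.testing.assert_array_equal(a.current, b.current)


def test_capacitive_current_offsets_segments(base_config):
    cfg = base_config.replace(double_layer_capacitance=2e-5, ks=0.0)
    vg, _ = pk.simulate_surface_cv(cfg)
    an, ca = pk.split_segments(vg)
    i_cap = cfg.double_layer_capacitance * cfg.electrode_area * cfg.scan_rate
    assert np.allclose(vg.current[an], i_cap)
    assert np.allclose(vg.current[ca], -i_cap)


def test_window_warning_flag(base_config):
    _, truth = pk.simulate_surface_cv(base_config)
    assert not truth.window_warning
    _, truth2 = pk.simulate_surface_cv(base_config.replace(
        e_start=0.05, e_switch=0.30))
    assert truth2.window_warning


def test_config_validation():
    good = dict(formal_potential=0.0, ks=1.0, coverage_total=1e-11,
                scan_rate=0.05, e_start=-0.2, e_switch=0.2)
    pk.SimulationConfig(**good)
    for bad in [dict(scan_rate=0.0), dict(e_switch=-0.2), dict(alpha=1.0),
                dict(ks=-1.0), dict(coverage_total=0.0), dict(noise_sd=-1e-9)]:
        with pytest.raises(ValueError):
            pk.SimulationConfig(**{**good, **bad})


def test_temperature_series_closed_forms():
    T = np.linspace(278, 318, 9)
    flat = pk.generate_temperature_series(0.1, 293.0, 0.0, 1, T)
    assert np.allclose(flat["E_V"], 0.1)
    df = pk.generate_temperature_series(0.1, 293.0, -96.485, 1, T)
    slope = np.polyfit(df["temperature_K"], df["E_V"], 1)[0]
    assert slope == pytest.approx(-96.485 / FARADAY, abs=1e-12)
    assert slope == pytest.approx(-1.000e-3, abs=1e-7)  # -1.000 mV/K
    one = pk.generate_temperature_series(0.10, 293.0, -96.485, 1, [293.0, 303.0, 313.0])
    assert one["E_V"].iloc[1] == pytest.approx(0.090, abs=1e-6)
    with pytest.raises(ValueError):
        pk.generate_temperature_series(0.1, 293.0, 0.0, 1, [])


def test_ph_series_limits(laccase_model):
    acid = pk.generate_ph_series(laccase_model, [2.0])
    assert acid["E_V"].iloc[0] == pytest.approx(laccase_model.E_lowpH, abs=1e-3)
    # alkaline asymptote: 0.059 * sum(pKa_red - pKa_ox) = 0.059 * 7.3
    assert laccase_model.total_span == pytest.approx(0.059 * 7.3, abs=1e-12)
    alk = pk.generate_ph_series(laccase_model, [13.0])
    assert alk["E_V"].iloc[0] == pytest.approx(
        laccase_model.E_lowpH - 0.431, abs=2e-3)  # pH 13 sits ~1 mV off the limit
    s1 = pk.generate_ph_series(laccase_model, np.arange(4, 12, 0.5), noise_sd=0.002, seed=5)
    s2 = pk.generate_ph_series(laccase_model, np.arange(4, 12, 0.5), noise_sd=0.002, seed=5)
    np.testing.assert_array_equal(s1["E_V"], s2["E_V"])
    with pytest.raises(ValueError):
        pk.generate_ph_series(laccase_model, [15.0])


def test_trumpet_series_reversible_and_monotone(base_config):
    rev = base_config.replace(ks=1e6)
    tr = pk.generate_trumpet_series(rev, [0.02, 0.05, 0.1, 0.2])
    assert np.all(np.abs(tr.E_pa - 0.097) < 1e-3)
    assert np.all(np.abs(tr.delta_Ep) < 1e-3)

    cfg = base_config.replace(e_start=0.097 - 0.4, e_switch=0.097 + 0.4)
    tr2 = pk.generate_trumpet_series(cfg, [0.02, 0.05, 0.1, 0.2, 0.5])
    dep = tr2.delta_Ep
    assert np.all(np.diff(dep) > -1e-5)  # non-decreasing in scan rate
    assert dep[-1] > 0.200  # irreversible branch reached at 0.5 V/s


def test_integrator_stable_at_extreme_rate_constants(base_config):
    """The exponential update tolerates ks spanning twelve decades."""
    for ks in (1e-3, 1e9):
        vg, _ = pk.simulate_surface_cv(base_config.replace(ks=ks))
        assert np.all(np.isfinite(vg.current))
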