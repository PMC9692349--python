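"""Laviron trumpet analysis, Arrhenius/Marcus, tunneling distances."""
import warnings

import numpy as np
import pytest

import pfvkit as pk
from pfvkit.constants import BOLTZMANN, FARADAY, GAS_CONSTANT, PLANCK
from pfvkit.errors import KineticsWarning


def _trumpet_from_sim(ks, m_inv_list, T=293.0, seed=0, noise_frac=None):
    cfg = pk.SimulationConfig(
        formal_potential=0.097, ks=ks, alpha=0.5, coverage_total=5e-11,
        scan_rate=0.05, e_start=0.097 - 0.45, e_switch=0.097 + 0.45,
        temperature=T, rng_seed=seed)
    f = FARADAY / (GAS_CONSTANT * T)
    rates = [m * ks / f for m in m_inv_list]
    return pk.generate_trumpet_series(cfg, rates, noise_fraction_of_peak=noise_frac)


def test_working_curve_shape(working_curve):
    """Strictly increasing, reversible limit near zero separation."""
    wc = working_curve
    assert np.all(np.diff(wc.delta_ep_dimless) > 0)
    assert wc.delta_ep_dimless[0] < 0.2  # -> 0 as m_inv -> 0
    assert wc.m_inv[0] <= 0.1


def test_working_curve_irreversible_asymptote(working_curve):
    """Cathodic-branch growth: d(dEp)/d(ln m_inv) -> 1/alpha + 1/(1-alpha)
    (= 4 at alpha = 0.5) in the irreversible limit."""
    wc = working_curve
    big = wc.m_inv > 50
    slope = np.polyfit(np.log(wc.m_inv[big]), wc.delta_ep_dimless[big], 1)[0]
    assert slope == pytest.approx(4.0, rel=0.05)


def test_working_curve_roundtrip_inversion(working_curve):
    """invert() is the inverse of the tabulated curve within interpolation error."""
    wc = working_curve
    mid = wc.m_inv[5:-5:4]
    dep = np.interp(np.log(mid), np.log(wc.m_inv), wc.delta_ep_dimless)
    back = wc.invert(dep)
    np.testing.assert_allclose(back, mid, rtol=1e-6)


def test_extract_ks_recovers_simulated_rate():
    """Noiseless trumpet at ks = 1 s^-1: working-curve extraction within 5%."""
    tr = _trumpet_from_sim(1.0, (0.8, 2, 4, 8, 12, 20))
    res = pk.extract_ks(tr)
    assert res.ks == pytest.approx(1.0, rel=0.05)
    assert res.method == "working_curve"
    assert res.rows_used >= 5


def test_extract_ks_grid_and_subset_invariance():
    """Any >= 4-row subset of a noiseless trumpet gives ks within 5%."""
    tr = _trumpet_from_sim(2.0, (1, 2, 4, 8, 12, 20))
    full = pk.extract_ks(tr).ks
    sub = pk.TrumpetData(scan_rate=tr.scan_rate[2:], E_pa=tr.E_pa[2:],
                         E_pc=tr.E_pc[2:], temperature=tr.temperature,
                         formal_potential=tr.formal_potential)
    assert pk.extract_ks(sub).ks == pytest.approx(full, rel=0.05)


@pytest.mark.parametrize("ks", [0.5, 1.0, 2.0, 5.0])
def test_methods_agree_across_ks_grid(ks):
    """Working-curve and irreversible-branch extractions agree within 20%
    and both sit within 15% of the simulated truth."""
    tr = _trumpet_from_sim(ks, (2, 4, 8, 16, 24, 32, 48))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", KineticsWarning)
        r_wc = pk.extract_ks(tr, method="working_curve")
        r_ir = pk.extract_ks(tr, method="irreversible_branch")
    assert r_wc.ks == pytest.approx(ks, rel=0.15)
    assert r_ir.ks == pytest.approx(ks, rel=0.15)
    assert r_ir.ks / r_wc.ks == pytest.approx(1.0, abs=0.20)
    assert r_ir.alpha == pytest.approx(0.5, abs=0.05)


def test_reversible_trumpet_gives_lower_bound_only():
    tr = _trumpet_from_sim(1e5, (1e-5, 2e-5, 4e-5, 8e-5))
    with pytest.warns(KineticsWarning):
        res = pk.extract_ks(tr)
    assert res.lower_bound_only
    assert res.ks is None
    assert res.ks_lower_bound > 0


def test_extract_ks_identity_on_curve_generated_trumpet(working_curve):
    """Trumpet rows synthesized from the working curve itself invert back
    to the generating ks (oracle round trip)."""
    wc = working_curve
    ks_true, T, e0 = 1.5, 298.15, 0.0
    f = FARADAY / (GAS_CONSTANT * T)
    m_inv = np.array([1.0, 3.0, 8.0, 20.0])
    dep = np.interp(np.log(m_inv), np.log(wc.m_inv), wc.delta_ep_dimless) / f
    tr = pk.TrumpetData(scan_rate=m_inv * ks_true / f,
                        E_pa=e0 + dep / 2, E_pc=e0 - dep / 2,
                        temperature=T, formal_potential=e0)
    assert pk.extract_ks(tr).ks == pytest.approx(ks_true, rel=0.01)


def test_arrhenius_closed_form():
    T = np.linspace(278, 318, 9)
    assert pk.arrhenius_activation(np.c_[T, np.full(T.size, 2.0)]) \
        == pytest.approx(0.0, abs=1e-9)
    ks = np.exp(29.42 - 2700.0 / T)
    dh = pk.arrhenius_activation(np.c_[T, ks])
    assert dh == pytest.approx(2700.0 * GAS_CONSTANT / 1000.0, rel=1e-9)  # 22.4 kJ/mol
    assert dh == pytest.approx(22.4, abs=0.1)
    with pytest.raises(ValueError):
        pk.arrhenius_activation(np.c_[T, -ks])


def test_arrhenius_noisy_recovery_coverage():
    """5% relative noise, 9 temperatures: the t-based 95% interval around the
    estimate covers the truth at the nominal rate across seeded replicates."""
    from scipy import stats as st

    T = np.linspace(278, 318, 9)
    truth = 2700.0 * GAS_CONSTANT / 1000.0
    tcrit = st.t.ppf(0.975, T.size - 2)
    rng = np.random.default_rng(8)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        ks = np.exp(29.42 - 2700.0 / T) * (1 + rng.normal(0, 0.05, T.size))
        est = pk.ArrheniusEstimator().fit(np.c_[T, np.abs(ks)])
        hits += abs(est.activation_enthalpy_ - truth) \
            < tcrit * est.activation_enthalpy_se_
    assert 0.90 <= hits / n_rep <= 0.99


def test_marcus_lambda():
    assert pk.marcus_lambda(0.0) == 0.0
    assert pk.marcus_lambda(22.4) == pytest.approx(89.6)
    with pytest.raises(ValueError):
        pk.marcus_lambda(-1.0)


def test_prefactor_kt_over_h():
    v290 = pk.prefactor_kT_over_h(290.0)
    assert v290 == pytest.approx(BOLTZMANN * 290.0 / PLANCK, rel=1e-12)
    assert round(v290 / 1e12) == 6  # the canonical 6e12 s^-1
    assert pk.prefactor_kT_over_h(298.15) == pytest.approx(6.21e12, rel=1e-3)
    assert pk.prefactor_kT_over_h(580.0) == pytest.approx(2 * v290, rel=1e-12)


def test_tunneling_distance_arithmetic():
    est = pk.tunneling_distance_interval(ks=1.0, activation_enthalpy=0.0,
                                         T=290.0, nu0=6e12, beta=1.0)
    assert est.total_distance_minus_r0 == pytest.approx(np.log(6e12), rel=1e-9)  # 29.4 A
    lo, hi = est.surface_to_center_interval
    assert hi - lo == pytest.approx(3.0)


def test_tunneling_interval_matches_reported_range():
    """ln nu0 - dH/(RT) - ln ks = 20.1 with d_sam = 19 A, r0 in [0, 3] A
    gives the 1.1-4.1 A surface-to-center interval."""
    ks = np.exp(np.log(6e12) - 20.1)
    est = pk.tunneling_distance_interval(ks=ks, activation_enthalpy=0.0,
                                         T=290.0, nu0=6e12)
    lo, hi = est.surface_to_center_interval
    assert lo == pytest.approx(1.1, abs=1e-9)
    assert hi == pytest.approx(4.1, abs=1e-9)


def test_tunneling_unphysical_floored_with_warning():
    ks = np.exp(np.log(6e12) - 18.0)  # D = 18 A < d_sam
    with pytest.warns(pk.errors.DistanceWarning):
        est = pk.tunneling_distance_interval(ks=ks, activation_enthalpy=0.0,
                                             T=290.0, nu0=6e12)
    assert est.surface_to_center_interval[0] == 0.0


def test_et_kinetics_summary_lambda_identity():
    ex = [pk.KsExtraction(ks=float(np.exp(29.42 - 2700.0 / T)), ks_se=None,
                          alpha=0.5, temperature=float(T), method="working_curve")
          for T in np.linspace(278, 318, 5)]
    summary = pk.et_kinetics_summary(ex)
    assert summary.reorganization_energy == pytest.approx(
        4.0 * summary.activation_enthalpy)
    assert summary.activation_enthalpy == pytest.approx(22.449, abs=0.01)


def test_working_curve_step_insensitivity():
    """Halving the simulation step changes the inverted ks by < 2%."""
    grid = np.geomspace(0.5, 30, 10)
    from pfvkit.kinetics import _CURVE_CACHE
    import pfvkit.simulate as sim
    wc1 = pk.build_working_curve(0.5, m_inv_grid=grid)
    tr = _trumpet_from_sim(1.0, (2, 6, 12, 20))
    f = FARADAY / (GAS_CONSTANT * tr.temperature)
    ks1 = np.exp(np.mean(np.log(
        [f * nu / wc1.invert(d * f) for nu, d in zip(tr.scan_rate, tr.delta_Ep)])))
    # rebuild the same grid from scratch at half the step
    _CURVE_CACHE.clear()
    orig = sim._SUBSTEP_V
    try:
        sim._SUBSTEP_V = orig / 2
        wc2 = pk.build_working_curve(0.5, m_inv_grid=grid)
    finally:
        sim._SUBSTEP_V = orig
        _CURVE_CACHE.clear()
    ks2 = np.exp(np.mean(np.log(
        [f * nu / wc2.invert(d * f) for nu, d in zip(tr.scan_rate, tr.delta_Ep)])))
    assert ks2 == pytest.approx(ks1, rel=0.02)
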