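import numpy as np
import pytest
from hypothesis import settings

import pfvkit as pk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

#: fitted titration constants of the covalently immobilized laccase
PKA_PAIRS = [(5.1, 7.5), (8.4, 10.9), (8.9, 11.3)]


@pytest.fixture(scope="session")
def base_config():
    """Quasi-reversible surface couple typical of the immobilized enzyme."""
    return pk.SimulationConfig(
        formal_potential=0.097, ks=1.0, alpha=0.5, coverage_total=5e-11,
        electrode_area=0.02, scan_rate=0.05, e_start=0.097 - 0.25,
        e_switch=0.097 + 0.25, temperature=293.0)


@pytest.fixture(scope="session")
def reversible_cv():
    """Nernstian-limit CV (huge ks, no capacitance, no noise)."""
    cfg = pk.SimulationConfig(
        formal_potential=0.0, ks=1e6, alpha=0.5, coverage_total=5e-11,
        electrode_area=0.02, scan_rate=0.05, e_start=-0.25, e_switch=0.25,
        temperature=298.15)
    vg, truth = pk.simulate_surface_cv(cfg)
    return vg, truth


@pytest.fixture(scope="session")
def quasireversible_cv(base_config):
    vg, truth = pk.simulate_surface_cv(base_config)
    return vg, truth


@pytest.fixture(scope="session")
def laccase_model():
    return pk.PhTitrationModel(E_lowpH=0.36, equilibria=PKA_PAIRS)


@pytest.fixture(scope="session")
def working_curve():
    return pk.build_working_curve(alpha=0.5)
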