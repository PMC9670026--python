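"""Forward-model correctness: closed forms vs an explicit ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from aggsense.kinetics import (
    InjectionProtocol,
    KineticParams,
    association_response,
    dissociation_response,
    molar_concentration,
    simulate_species_trace,
)
from aggsense.presets import AGGREGATE_KINETICS, MONOMER_KINETICS, default_monomer
from tests.conftest import make_protocol

ALL_PARAM_SETS = [
    pytest.param(p, id=f"{name}-pH{ph}")
    for name, table in (("monomer", MONOMER_KINETICS), ("aggregate", AGGREGATE_KINETICS))
    for ph, p in table.items()
]


@pytest.mark.parametrize(
    "mass,mw,expected",
    [(0.0, 150000.0, 0.0), (0.45, 150000.0, 3.0e-6), (0.15, 300000.0, 5.0e-7)],
)
def test_molar_concentration_unit_chain(mass, mw, expected):
    assert molar_concentration(mass, mw) == pytest.approx(expected, rel=1e-12)


def test_molar_concentration_rejects_bad_inputs():
    with pytest.raises(ValueError):
        molar_concentration(1.0, 0.0)
    with pytest.raises(ValueError):
        molar_concentration(-0.1, 150000.0)


@pytest.mark.parametrize("params", ALL_PARAM_SETS)
def test_association_matches_ode_integration(params):
    """Closed-form association equals explicit integration of
    dR/dt = k_on*C*(r_max - R) - k_off*R to < 1e-6 relative error."""
    conc, r_max = 3e-6, 1000.0
    t = np.linspace(0.0, 100.0, 201)
    sol = solve_ivp(
        lambda _t, r: params.k_on * conc * (r_max - r) - params.k_off * r,
        (0.0, 100.0), [0.0], t_eval=t, rtol=1e-10, atol=1e-12,
    )
    closed = association_response(params, conc, r_max, t)
    assert np.max(np.abs(closed - sol.y[0])) < 1e-6 * np.max(closed)


def test_association_zero_conc_and_equilibrium_symmetry():
    p = KineticParams(k_on=3.0e4, k_off=1.0e-2)
    assert association_response(p, 0.0, 1000.0, 50.0) == 0.0
    # at C = K_D the equilibrium response is r_max / 2
    kd = p.k_d
    t_eq = 20.0 / (p.k_on * kd + p.k_off)
    assert association_response(p, kd, 1000.0, t_eq) == pytest.approx(500.0, abs=1e-3)


@pytest.mark.parametrize("params", ALL_PARAM_SETS)
def test_association_reaches_equilibrium_plateau(params):
    conc, r_max = 3e-6, 1000.0
    r_eq = r_max * conc / (conc + params.k_d)
    t_eq = 20.0 / (params.k_on * conc + params.k_off)
    assert abs(association_response(params, conc, r_max, t_eq) - r_eq) < 1e-6 * r_max


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    c1=st.floats(1e-9, 1e-4), c2=st.floats(1e-9, 1e-4),
    t=st.floats(0.1, 500.0),
)
def test_association_strictly_increasing_in_concentration(c1, c2, t):
    p = KineticParams(k_on=3.0e4, k_off=1.0e-2)
    lo, hi = sorted([c1, c2])
    if hi / lo < 1 + 1e-9:
        return
    assert association_response(p, hi, 1000.0, t) > association_response(p, lo, 1000.0, t)


def test_dissociation_identities():
    assert dissociation_response(500.0, 0.0, 1e4) == 500.0
    k = 1.0e-2
    assert dissociation_response(500.0, k, np.log(2) / k) == pytest.approx(250.0)
    assert dissociation_response(500.0, k, 190.0) == pytest.approx(
        500.0 * np.exp(-1.9), rel=1e-12
    )
    # initial slope equals -k_off * r0
    eps = 1e-6
    slope = (dissociation_response(500.0, k, eps) - 500.0) / eps
    assert slope == pytest.approx(-k * 500.0, rel=1e-4)


def test_negative_time_rejected():
    p = KineticParams(k_on=1e4, k_off=1e-3)
    with pytest.raises(ValueError):
        association_response(p, 1e-6, 1000.0, -1.0)
    with pytest.raises(ValueError):
        dissociation_response(100.0, 1e-3, -0.5)


class TestSimulateSpeciesTrace:
    def test_zero_concentration_gives_zero_trace(self, monomer):
        proto = make_protocol(3.8, total=0.45, fraction=1.0)  # monomer conc = 0
        trace = simulate_species_trace(monomer, proto)
        assert np.all(trace.response == 0.0)

    def test_baseline_zero_and_phase_continuity(self, monomer):
        proto = make_protocol(3.8, total=0.45, fraction=0.0)
        trace = simulate_species_trace(monomer, proto)
        baseline = trace.response[trace.time < proto.t_baseline_end]
        assert np.all(baseline == 0.0)
        # association endpoint and dissociation start agree (continuity)
        i = int(np.searchsorted(trace.time, proto.t_assoc_end))
        assert abs(trace.response[i] - trace.response[i - 1]) < 0.02 * trace.response[i]

    def test_flat_dissociation_at_ph74(self, monomer):
        """With k_off = 2.9e-5 s^-1 the dissociation loses < 1 % over 190 s."""
        proto = make_protocol(7.4, total=0.45, fraction=0.0)
        trace = simulate_species_trace(monomer, proto)
        r_start = trace.response[trace.time == proto.t_assoc_end][0]
        r_end = trace.response[-1]
        assert r_end >= 0.99 * r_start
        assert r_end / r_start == pytest.approx(np.exp(-2.9e-5 * 190.0), rel=1e-6)

    def test_missing_ph_is_configuration_error(self, monomer):
        proto = InjectionProtocol(ph=5.0, concentrations={"monomer": 0.45})
        with pytest.raises(KeyError):
            simulate_species_trace(monomer, proto)


def test_kinetic_params_validation():
    with pytest.raises(ValueError):
        KineticParams(k_on=0.0, k_off=1e-3)
    with pytest.raises(ValueError):
        KineticParams(k_on=1e4, k_off=-1e-3)
    assert KineticParams(k_on=2e4, k_off=1e-2).k_d == pytest.approx(5e-7)


def test_protocol_validation():
    with pytest.raises(ValueError):
        InjectionProtocol(t_baseline_end=120.0)  # baseline after association end
    with pytest.raises(ValueError):
        InjectionProtocol(concentrations={"monomer": -0.1})
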