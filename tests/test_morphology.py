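"""Electrical substrate: construction, cable solutions, resting state."""

import numpy as np
import pytest

from spnlearn.morphology import (
    Morphology,
    PassiveParams,
    build_surrogate_morphology,
    detect_somatic_spikes,
    input_impedance,
)
from spnlearn._kernel import hines_factorization
from spnlearn.model import SPNModel


def test_construction_counts():
    m = build_surrogate_morphology(n_dendrites=2, dendrite_length=200.0,
                                   segments_per_dendrite=10)
    assert m.n_comp == 21
    assert m.somatic_distance.max() == pytest.approx(190.0)  # midpoint of last segment
    m30 = build_surrogate_morphology(n_dendrites=30, dendrite_length=200.0,
                                     segments_per_dendrite=10)
    assert m30.n_comp == 301


def test_geometry_invariants(morphology):
    m = morphology
    assert np.sum(m.parent == -1) == 1  # exactly one soma
    assert np.all(m.length > 0) and np.all(m.diameter > 0)
    assert m.somatic_distance[0] == 0.0
    # non-increasing diameter along every root-to-tip path
    for d in range(12):
        idx = m.dendrite_compartments(d)
        assert np.all(np.diff(m.diameter[idx]) <= 1e-12)


@pytest.mark.parametrize("kwargs", [
    dict(n_dendrites=1),
    dict(dendrite_length=100.0),
    dict(segments_per_dendrite=3),
    dict(segments_per_dendrite=4, dendrite_length=200.0),  # 50 um segments
    dict(taper=0.0),
])
def test_construction_guards(kwargs):
    with pytest.raises(ValueError):
        build_surrogate_morphology(**kwargs)


def test_hines_solve_matches_dense(morphology):
    m = morphology
    dt = 0.1
    low, upc, dtilde = hines_factorization(m.parent, m.g_axial, m.cm, dt)
    n = m.n_comp
    M = np.eye(n)
    for i in range(1, n):
        p = m.parent[i]
        g = m.g_axial[i]
        M[i, i] += dt * g / m.cm[i]
        M[p, p] += dt * g / m.cm[p]
        M[i, p] -= dt * g / m.cm[i]
        M[p, i] -= dt * g / m.cm[p]
    rng = np.random.default_rng(0)
    b = rng.normal(size=n)
    x_ref = np.linalg.solve(M, b)
    bb = b.copy()
    for i in range(n - 1, 0, -1):
        bb[m.parent[i]] -= upc[i] * bb[i]
    x = np.zeros(n)
    x[0] = bb[0] / dtilde[0]
    for i in range(1, n):
        x[i] = (bb[i] - low[i] * x[m.parent[i]]) / dtilde[i]
    np.testing.assert_allclose(x, x_ref, rtol=1e-12, atol=1e-12)


def test_resting_potential_in_spn_band(morphology):
    v = morphology.resting_potential()
    assert np.all(v >= -90.0) and np.all(v <= -80.0)


def test_passive_steady_state_matches_analytic():
    """With KIR off, the integrator's steady state matches the exact linear
    cable solution to within 0.1 % of the deflection."""
    m = build_surrogate_morphology(n_dendrites=2)
    model = SPNModel(morphology=m, dt=0.02)
    model.finalize()
    site = m.compartment_at(0, 110.0)
    inj = np.zeros(m.n_comp)
    inj[site] = 0.02
    # analytic: linear solve of the passive system (KIR off)
    v_ref = m.steady_state(i_inj=inj, kir=False) - m.steady_state(kir=False)
    # integrator with every non-leak conductance disabled
    m.g_kir[:] = 0.0
    m.g_kas[:] = 0.0
    model.g_lva_sh[:] = 0.0
    model.g_hva_sh[:] = 0.0
    model.refresh_parameters()
    model._rest_state = model._make_rest_state()
    model._relax_rest_state(500.0)
    st = model.rest_state()
    v0 = st.V.copy()
    model.run_window(2000.0, state=st, i_inj=inj)
    defl = st.V - v0
    err = np.abs(defl - v_ref).max() / np.abs(v_ref).max()
    assert err < 1e-3


def test_zero_input_fixed_point(calibrated_model):
    st = calibrated_model.rest_state()
    v0 = st.V.copy()
    calibrated_model.run_window(50.0, state=st)
    assert np.abs(st.V - v0).max() < 1e-9


def test_current_injection_matches_input_resistance(morphology):
    model = SPNModel(morphology=morphology, dt=0.1)
    model.finalize()
    st = model.rest_state()
    v0 = st.V[0]
    inj = np.zeros(morphology.n_comp)
    inj[0] = -0.1
    model.run_window(3000.0, state=st, i_inj=inj)
    r_in = input_impedance(morphology, 0, i_test=-0.1)
    assert st.V[0] - v0 == pytest.approx(-0.1 * r_in, rel=0.02)


def test_relaxation_back_to_rest(morphology):
    model = SPNModel(morphology=morphology, dt=0.1)
    model.finalize()
    st = model.rest_state()
    v0 = st.V.copy()
    inj = np.zeros(morphology.n_comp)
    inj[0] = -0.1
    model.run_window(200.0, state=st, i_inj=inj, inj_window=(0.0, 100.0))
    # 100 ms after the step turns off: > 5 membrane time constants
    assert np.abs(st.V - v0).max() < 0.5


def test_impedance_ordering(morphology):
    """Soma has the smallest impedance; impedance grows monotonically with
    distance along an unbranched dendrite (brute-force over all sites)."""
    z = np.array([input_impedance(morphology, i) for i in range(morphology.n_comp)])
    assert np.argmin(z) == 0
    idx = morphology.dendrite_compartments(0)
    assert np.all(np.diff(z[idx]) > 0)


def test_charge_conservation():
    """All channels off, sealed ends: injected charge equals the capacitive
    charge change."""
    m = build_surrogate_morphology(n_dendrites=2)
    m.g_leak[:] = 0.0
    m.g_kir[:] = 0.0
    m.g_kas[:] = 0.0
    model = SPNModel(morphology=m, dt=0.1)
    model.vgcc.g_lva_shaft = 0.0
    model.vgcc.g_hva_shaft = 0.0
    model.spike.threshold = 1e6  # no spiking during the charge test
    model.finalize()
    st = model.rest_state()
    v0 = st.V.copy()
    inj = np.zeros(m.n_comp)
    inj[3] = 0.05
    duration = 100.0
    model.run_window(duration, state=st, i_inj=inj)
    injected = 0.05 * duration                      # nA*ms = pC
    stored = np.sum(m.cm * (st.V - v0))             # nF*mV = pC
    assert stored == pytest.approx(injected, rel=1e-6)


def test_spike_detection_rules():
    dt = 0.1
    flat = np.full(1000, -85.0)
    assert detect_somatic_spikes(flat, dt).size == 0
    ramp = np.linspace(-80.0, -20.0, 1000)
    spikes = detect_somatic_spikes(ramp, dt, threshold=-40.0)
    assert spikes.size == 1
    # two crossings 3 ms apart with 5 ms refractory -> one spike
    v = np.full(200, -85.0)
    v[10:15] = -30.0
    v[40:45] = -30.0
    spikes = detect_somatic_spikes(v, dt, threshold=-40.0, refractory=5.0)
    assert spikes.size == 1
    assert detect_somatic_spikes(np.empty(0), dt).size == 0


def test_json_round_trip(morphology):
    text = morphology.to_json()
    m2 = Morphology.from_json(text)
    np.testing.assert_allclose(m2.somatic_distance, morphology.somatic_distance)
    np.testing.assert_allclose(m2.g_axial, morphology.g_axial)
    assert m2.passive == morphology.passive
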