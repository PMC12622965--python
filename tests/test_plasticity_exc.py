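"""Excitatory rule: kernel math, LTP/LTD arithmetic, metaplasticity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spnlearn.plasticity_exc import (
    ExcPlasticityParams,
    LtpKernelState,
    apply_excitatory_feedback,
    ltd_delta,
    ltp_delta,
    metaplasticity_shift,
    sigmoid,
    sigmoid_deriv,
)

P = ExcPlasticityParams()


def test_sigmoid_closed_form():
    assert sigmoid(0.02, 0.02, 1e3) == pytest.approx(0.5, abs=1e-12)
    assert sigmoid(-10.0, 0.02, 1e3) == pytest.approx(0.0, abs=1e-12)
    assert sigmoid(10.0, 0.02, 1e3) == pytest.approx(1.0, abs=1e-12)
    # symmetry identity on a grid
    x = np.linspace(-0.05, 0.05, 101)
    np.testing.assert_allclose(
        sigmoid(0.02 + x, 0.02, 1e3) + sigmoid(0.02 - x, 0.02, 1e3), 1.0,
        rtol=0, atol=1e-10,
    )


def test_sigmoid_numerically_stable():
    assert sigmoid(1e3, 0.02, 1e3) == 1.0
    assert sigmoid(-1e3, 0.02, 1e3) == pytest.approx(0.0)
    assert np.isfinite(sigmoid_deriv(1e3, 0.02, 1e3))


def test_sigmoid_deriv_peak_and_symmetry():
    assert sigmoid_deriv(0.02, 0.02, 1e3) == pytest.approx(250.0, abs=1e-10)
    x = np.linspace(0.0, 0.04, 81)
    np.testing.assert_allclose(
        sigmoid_deriv(0.02 + x, 0.02, 1e3), sigmoid_deriv(0.02 - x, 0.02, 1e3),
        rtol=1e-7, atol=1e-12,
    )


def test_sigmoid_deriv_matches_finite_difference():
    ca = np.linspace(0.005, 0.035, 61)
    h = 1e-7
    fd = (sigmoid(ca + h, 0.02, 1e3) - sigmoid(ca - h, 0.02, 1e3)) / (2 * h)
    np.testing.assert_allclose(sigmoid_deriv(ca, 0.02, 1e3), fd, rtol=1e-5, atol=1e-6)


def test_ltp_delta_arithmetic():
    # at the kernel midpoint: eta * beta/4 * integration window
    expected = P.eta_ltp * 250.0 * P.ltp_duration
    assert ltp_delta(P.theta_ltp0, P.theta_ltp0, P) == pytest.approx(expected)
    # the full-cue variant of the same arithmetic: eta * 250 * 50 = 0.1875
    p50 = ExcPlasticityParams(ltp_duration=50.0)
    assert ltp_delta(0.02, 0.02, p50) == pytest.approx(0.1875)
    # tail decay
    assert ltp_delta(0.02 + 25.0 / P.beta_ltp, 0.02, P) < 1e-7
    # kernel symmetry
    assert ltp_delta(0.025, 0.02, P) == pytest.approx(ltp_delta(0.015, 0.02, P))


def test_ltp_delta_rejects_negative_calcium():
    with pytest.raises(ValueError):
        ltp_delta(-1e-3, 0.02, P)


def test_ltd_delta_arithmetic():
    # below the 70 nM threshold the steep sigmoid gates LTD to a negligible
    # level (the transition is ~10 nM wide, so 20 nM below threshold the
    # change is ~1e-7 weight units — irrelevant for learning)
    assert ltd_delta(5e-5, 0.25, P) < 1e-5
    assert ltd_delta(5e-5, 0.25, P) < 5e-2 * ltd_delta(2e-4, 0.25, P)
    # plug-in arithmetic above threshold
    ca = 2e-4
    expected = (P.eta_ltd * ca * sigmoid(ca, P.theta_ltd, P.beta_ltd)
                * 0.25 * P.feedback_duration)
    assert ltd_delta(ca, 0.25, P) == pytest.approx(expected)
    assert sigmoid(ca, P.theta_ltd, P.beta_ltd) > 0.999
    # multiplicative rule: zero weight cannot go negative
    assert ltd_delta(2e-4, 0.0, P) == 0.0


def test_metaplasticity_signs_and_ratio():
    ca = 0.02
    peak = metaplasticity_shift(ca, 0.02, +1, P)
    pause = metaplasticity_shift(ca, 0.02, -1, P)
    assert peak < 0 < pause
    assert abs(peak) == pytest.approx(P.eta_s_ltp * (P.beta_mp / 4.0)
                                      * P.feedback_duration * P.mp_rate_factor)
    # the pause shift is exactly four times the peak shift
    assert pause == pytest.approx(4.0 * abs(peak), rel=1e-12)


def test_metaplasticity_toggle():
    p = ExcPlasticityParams(metaplasticity_enabled=False)
    assert np.all(metaplasticity_shift(0.02, 0.02, +1, p) == 0.0)
    assert np.all(metaplasticity_shift(0.02, 0.02, -1, p) == 0.0)


def test_param_invariants_enforced():
    with pytest.raises(ValueError):
        ExcPlasticityParams(eta_s_ltd=1e-7)  # must be 4x eta_s_ltp
    with pytest.raises(ValueError):
        ExcPlasticityParams(beta_mp=2e3)     # must be wider than the LTP kernel


def test_basal_dopamine_bit_identical():
    rng = np.random.default_rng(0)
    w = rng.uniform(0.1, 0.4, 20)
    w0 = w.copy()
    state = LtpKernelState.initial(20, P)
    th0 = state.theta_ltp.copy()
    ca_n = rng.uniform(0.0, 0.04, 20)
    ca_l = rng.uniform(0.0, 0.03, 20)
    eligible = np.ones(20, dtype=bool)
    apply_excitatory_feedback(w, state, ca_n, ca_l, eligible, 0, P)
    assert np.array_equal(w, w0)
    assert np.array_equal(state.theta_ltp, th0)


def test_ineligible_synapses_untouched():
    w = np.full(4, 0.25)
    state = LtpKernelState.initial(4, P)
    eligible = np.array([True, True, False, False])
    apply_excitatory_feedback(w, state, np.full(4, 0.02), np.full(4, 0.02),
                              eligible, +1, P)
    assert np.all(w[2:] == 0.25)
    assert np.all(w[:2] > 0.25)
    assert np.all(state.theta_ltp[2:] == P.theta_ltp0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_weight_bounds_invariant(seed):
    """0 <= w <= w_cap after any random feedback sequence."""
    rng = np.random.default_rng(seed)
    n = 8
    p = ExcPlasticityParams(rate_factor=3.0, w_cap=0.38)
    w = rng.uniform(0.0, p.w_cap, n)
    state = LtpKernelState.initial(n, p)
    for _ in range(30):
        da = int(rng.choice([-1, 0, 1]))
        apply_excitatory_feedback(
            w, state,
            rng.uniform(0.0, 0.06, n), rng.uniform(0.0, 0.06, n),
            rng.random(n) < 0.7, da, p,
        )
        assert np.all(w >= 0.0) and np.all(w <= p.w_cap + 1e-15)
        assert np.all(state.theta_ltp > 0.0)


def test_repeated_peaks_self_stabilize():
    """Fixed calcium slightly above the midpoint: the kernel slides below the
    calcium level and the weight increments shrink toward zero."""
    p = ExcPlasticityParams(ltp_duration=50.0)
    ca = np.array([0.022])
    w = np.array([0.25])
    state = LtpKernelState(theta_ltp=np.array([0.02]))
    deltas = []
    for _ in range(400):
        before = w[0]
        apply_excitatory_feedback(w, state, ca, np.zeros(1), np.ones(1, bool), +1, p)
        deltas.append(w[0] - before)
    assert state.theta_ltp[0] < ca[0]          # midpoint moved below the calcium
    assert deltas[-1] < 1e-3 * max(deltas)     # potentiation has shut itself off
    assert w[0] <= p.w_cap


def test_pause_then_peak_nets_upward_theta():
    """One pause plus one peak at the same calcium raises the midpoint
    (the pause shift is four times larger)."""
    state = LtpKernelState(theta_ltp=np.array([0.02]))
    w = np.array([0.25])
    ca = np.array([0.02])
    apply_excitatory_feedback(w, state, ca, np.zeros(1), np.ones(1, bool), -1, P)
    apply_excitatory_feedback(w, state, ca, np.zeros(1), np.ones(1, bool), +1, P)
    assert state.theta_ltp[0] > 0.02
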