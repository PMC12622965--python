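"""Inhibitory rule: Omega function, sign table, sliding thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spnlearn.plasticity_inh import (
    InhPlasticityParams,
    InhThresholdState,
    apply_inhibitory_update,
    inh_weight_delta,
    omega,
    update_theta_high,
    update_theta_low,
)

P = InhPlasticityParams()
TL, TH = P.theta_low_init, P.theta_high_init


def test_omega_plateaus():
    # the sigmoid width is 1/beta_inh ~ 4e-4 mM, so at the initial threshold
    # scale the three zones are soft shoulders
    assert omega(1e-8, TL, TH, -1, 3, P.beta_inh) == pytest.approx(0.0, abs=0.05)
    mid = 0.5 * (TL + TH)
    assert omega(mid, TL, TH, -1, 3, P.beta_inh) == pytest.approx(-1.0, abs=0.25)
    assert omega(10 * TH, TL, TH, -1, 3, P.beta_inh) == pytest.approx(2.0, abs=1e-6)


def test_sign_table_active_and_inactive():
    """Weight-change sign over a calcium grid reproduces the BCM-like table:
    active synapses potentiate between the thresholds and depress above the
    high one; inactive synapses do the opposite; below the low threshold
    nothing changes."""
    thetas = (np.array([TL]), np.array([TH]))
    w = 0.002  # intermediate weight
    low_ca, mid_ca, high_ca = TL / 10, 0.5 * (TL + TH), 4 * TH
    d_mid = inh_weight_delta(mid_ca, w, True, thetas, P)
    # active: potentiate between the thresholds, depress above the high one,
    # little change below the low one (soft zones: compare to the mid zone)
    assert abs(inh_weight_delta(low_ca, w, True, thetas, P)) < 0.1 * abs(d_mid)
    assert d_mid > 0
    assert inh_weight_delta(high_ca, w, True, thetas, P) < 0
    # inactive: mirrored
    assert abs(inh_weight_delta(low_ca, w, False, thetas, P)) < 0.1 * abs(d_mid)
    assert inh_weight_delta(mid_ca, w, False, thetas, P) < 0
    assert inh_weight_delta(high_ca, w, False, thetas, P) > 0


def test_soft_bounds_vanish_at_limits():
    thetas = (np.array([TL]), np.array([TH]))
    mid_ca = 0.5 * (TL + TH)
    assert inh_weight_delta(mid_ca, 0.0, True, thetas, P) == 0.0
    assert inh_weight_delta(mid_ca, P.w_inh_max, True, thetas, P) == 0.0
    # fastest at the middle of the range
    d_mid = abs(inh_weight_delta(mid_ca, P.w_inh_max / 2, True, thetas, P))
    d_low = abs(inh_weight_delta(mid_ca, P.w_inh_max / 10, True, thetas, P))
    assert d_mid > d_low


def test_theta_high_shift_signs():
    thetas = (np.array([TL]), np.array([TH]))
    assert update_theta_high(4 * TH, thetas, P) > 0      # rises toward high calcium
    mid_shift = update_theta_high(0.5 * (TL + TH), thetas, P)
    assert mid_shift < 0                                 # relaxes downward
    assert abs(update_theta_high(TL / 10, thetas, P)) < 0.2 * abs(mid_shift)


def test_theta_low_shift_signs():
    thetas = (np.array([TL]), np.array([TH]))
    # ca + c between the thresholds -> omega ~ -2, eta negative -> rises
    ca_between = 0.5 * (TL + TH) - P.c
    if ca_between > 0:
        assert update_theta_low(ca_between, thetas, P) > 0
    # ca + c far above theta_high -> omega ~ +1 -> falls
    assert update_theta_low(10 * TH, thetas, P) < 0
    # far below, in the sharp-zone regime of grown thresholds: nothing
    big = (np.array([20 * P.c]), np.array([40 * P.c]))
    assert abs(update_theta_low(0.0, big, P)) < 1e-7


def test_quiescent_calcium_changes_little():
    """Baseline calcium far below a trained threshold pair changes neither
    weights nor thresholds appreciably (the zones sharpen as the thresholds
    grow away from the baseline)."""
    n = 6
    w = np.full(n, 0.002)
    state = InhThresholdState(theta_low=np.full(n, 4e-3), theta_high=np.full(n, 9e-3))
    w0, tl0, th0 = w.copy(), state.theta_low.copy(), state.theta_high.copy()
    ca = np.full(n, 5e-5)   # resting baseline
    apply_inhibitory_update(w, state, ca, np.zeros(n, bool), P)
    assert np.abs(w - w0).max() < 1e-9
    assert np.abs(state.theta_low - tl0).max() < 1e-5
    assert np.abs(state.theta_high - th0).max() < 1e-4


def test_theta_high_tracks_maximum_of_stationary_sequence():
    """Under a repeating calcium sequence, theta_high converges to a
    neighborhood of the sequence maximum (fixed point of the shift rule)."""
    rng = np.random.default_rng(3)
    ca_max = 8e-3
    seq = np.array([ca_max, 0.3 * ca_max, 0.5 * ca_max])
    w = np.array([0.002])
    state = InhThresholdState.initial(1, P)
    for i in range(3000):
        ca = np.array([seq[i % 3]])
        apply_inhibitory_update(w, state, ca, np.ones(1, bool), P)
    assert state.theta_high[0] == pytest.approx(ca_max, rel=0.35)
    assert state.theta_low[0] < state.theta_high[0]


def test_bimodal_contrast_enhancement():
    """Two synapses at one site with a bimodal calcium stream: the synapse
    active during the high-calcium stimulus depresses, the one inactive
    during it potentiates."""
    high, mid = 8e-3, 2e-3
    w = np.array([0.002, 0.002])
    state = InhThresholdState.initial(2, P)
    for i in range(1500):
        if i % 2 == 0:   # stimulus A: high calcium, synapse 0 active
            apply_inhibitory_update(w, state, np.array([high, high]),
                                    np.array([True, False]), P)
        else:            # stimulus B: mid calcium, synapse 1 active
            apply_inhibitory_update(w, state, np.array([mid, mid]),
                                    np.array([False, True]), P)
    assert w[1] > w[0]


def test_dopamine_independence_and_determinism():
    """The update has no dopamine argument at all; identical replay is
    bit-identical."""
    rng = np.random.default_rng(11)
    cas = rng.uniform(0.0, 3e-3, (50, 4))
    acts = rng.random((50, 4)) < 0.5

    def run():
        w = np.full(4, 0.002)
        state = InhThresholdState.initial(4, P)
        for ca, act in zip(cas, acts):
            apply_inhibitory_update(w, state, ca, act, P)
        return w, state.theta_low, state.theta_high

    w1, tl1, th1 = run()
    w2, tl2, th2 = run()
    assert np.array_equal(w1, w2) and np.array_equal(tl1, tl2) and np.array_equal(th1, th2)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_inh_weight_bounds_invariant(seed):
    rng = np.random.default_rng(seed)
    n = 5
    w = rng.uniform(0, P.w_inh_max, n)
    state = InhThresholdState.initial(n, P)
    for _ in range(40):
        apply_inhibitory_update(w, state, rng.uniform(0, 5e-3, n),
                                rng.random(n) < 0.5, P)
        assert np.all(w >= 0) and np.all(w <= P.w_inh_max)
        assert np.all(state.theta_low <= state.theta_high - P.theta_gap + 1e-15)
        assert np.all(state.theta_low > 0)
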