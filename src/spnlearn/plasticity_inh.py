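"""Calcium-threshold inhibitory plasticity (BCM-style), dopamine independent.

The rule passively tracks the local excitatory drive through the shaft
voltage-gated calcium pool [Ca]_v and uses a two-sigmoid function Omega with
two sliding thresholds:

* active synapses (those that received an event during the stimulus) are
  potentiated when calcium falls between the thresholds and depressed above
  the high threshold;
* inactive synapses follow the mirrored rule (sign of the learning rate);
* below the low threshold essentially nothing changes.

The soft-bound factor ``w (w_max - w)`` makes intermediate weights the most
plastic and pins the ends of the range.  The thresholds themselves slide:
``theta_high`` tracks the largest observed calcium level, ``theta_low``
settles below it (the offset ``c`` makes the two threshold-update curves
cross zero together).  The net effect is contrast enhancement: features that
drive the dendrite hardest lose their inhibition, all others gain it.

Like the excitatory rule, updates are per-stimulus events using the peak
calcium since onset, scaled by a 50 ms update window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plasticity_exc import sigmoid

__all__ = [
    "InhPlasticityParams",
    "InhThresholdState",
    "omega",
    "inh_weight_delta",
    "update_theta_high",
    "update_theta_low",
    "apply_inhibitory_update",
]


@dataclass
class InhPlasticityParams:
    beta_inh: float = 2.5e3          # 1/mM
    eta_act_active: float = -0.055   # 1/(uS ms) — negative: see Omega signs
    eta_act_inactive: float = 0.055  # 1/(uS ms)
    a_inh: float = -1.0
    b_inh: float = 3.0
    w_inh_max: float = 0.005         # uS
    eta_inh_high: float = 9e-4       # mM/ms
    a_inh_high: float = -1.0
    b_inh_high: float = 3.0
    eta_inh_low: float = -5e-5       # mM/ms
    a_inh_low: float = -2.0
    b_inh_low: float = 3.0
    c: float = 6e-4                  # mM, calcium offset of the low-threshold rule
    update_window: float = 50.0      # ms, weight-update event window
    # the threshold rates are per ms in units of mM; integrated over the full
    # 50 ms window a single event would move a threshold by 0.045 mM — far
    # beyond the calcium scale itself.  One equivalent millisecond per event
    # gives threshold drifts over tens of stimuli, as in the published
    # threshold trajectories.
    theta_window: float = 1.0        # ms, threshold-update event window
    # initial thresholds sit between the resting [Ca]_v baseline and the
    # evoked peaks, far enough apart (>= a few sigmoid widths, 1/beta_inh)
    # for the potentiation/depression zones to exist
    theta_low_init: float = 1.5e-3   # mM
    theta_high_init: float = 4e-3    # mM
    theta_gap: float = 1e-5          # mM, enforced theta_low <= theta_high - gap
    rate_factor: float = 1.0         # shared global factor with the excitatory rule

    def __post_init__(self):
        if self.w_inh_max <= 0:
            raise ValueError("w_inh_max must be positive")
        if abs(self.eta_act_active + self.eta_act_inactive) > 1e-15:
            raise ValueError("active and inactive rates must be opposite")


@dataclass
class InhThresholdState:
    theta_low: np.ndarray    # mM, per synapse
    theta_high: np.ndarray   # mM, per synapse

    @classmethod
    def initial(cls, n: int, params: InhPlasticityParams) -> "InhThresholdState":
        return cls(
            theta_low=np.full(n, params.theta_low_init),
            theta_high=np.full(n, params.theta_high_init),
        )


def omega(ca, theta_low, theta_high, a, b, beta_inh):
    """a * sigma(ca; theta_low) + b * sigma(ca; theta_high).

    With a = -1, b = 3 this is ~0 below theta_low, ~-1 between the thresholds
    and ~2 above theta_high.
    """
    return a * sigmoid(ca, theta_low, beta_inh) + b * sigmoid(ca, theta_high, beta_inh)


def inh_weight_delta(ca_v_peak, w_inh, active, state_or_thetas,
                     params: InhPlasticityParams):
    """Signed weight change (uS); vanishes exactly at w = 0 and w = w_max."""
    tl, th = _thetas(state_or_thetas)
    eta = params.eta_act_active if active else params.eta_act_inactive
    om = omega(ca_v_peak, tl, th, params.a_inh, params.b_inh, params.beta_inh)
    w = np.asarray(w_inh, dtype=float)
    return (
        eta * params.rate_factor * om * w * (params.w_inh_max - w) * params.update_window
    )


def update_theta_high(ca_v_peak, state_or_thetas, params: InhPlasticityParams):
    """Shift of theta_high toward the highest observed calcium level."""
    tl, th = _thetas(state_or_thetas)
    om = omega(ca_v_peak, tl, th, params.a_inh_high, params.b_inh_high, params.beta_inh)
    return params.eta_inh_high * params.rate_factor * om * params.theta_window


def update_theta_low(ca_v_peak, state_or_thetas, params: InhPlasticityParams):
    """Shift of theta_low toward a level below the maximum (offset by c)."""
    tl, th = _thetas(state_or_thetas)
    om = omega(
        np.asarray(ca_v_peak, dtype=float) + params.c,
        tl, th, params.a_inh_low, params.b_inh_low, params.beta_inh,
    )
    return params.eta_inh_low * params.rate_factor * om * params.theta_window


def _thetas(state_or_thetas):
    if isinstance(state_or_thetas, InhThresholdState):
        return state_or_thetas.theta_low, state_or_thetas.theta_high
    return state_or_thetas


def apply_inhibitory_update(
    w_inh: np.ndarray,
    state: InhThresholdState,
    ca_v_peaks: np.ndarray,
    active: np.ndarray,
    params: InhPlasticityParams,
) -> None:
    """One per-stimulus update of every inhibitory synapse, in place.

    Unlike the excitatory rule there is no eligibility restriction: inactive
    synapses take the mirrored branch.  No dopamine enters anywhere.
    """
    act = np.asarray(active, dtype=bool)
    ca = np.asarray(ca_v_peaks, dtype=float)
    om_w = omega(ca, state.theta_low, state.theta_high,
                 params.a_inh, params.b_inh, params.beta_inh)
    eta = np.where(act, params.eta_act_active, params.eta_act_inactive)
    dw = (
        eta * params.rate_factor * om_w
        * w_inh * (params.w_inh_max - w_inh) * params.update_window
    )
    w_inh[:] = np.clip(w_inh + dw, 0.0, params.w_inh_max)
    d_high = update_theta_high(ca, state, params)
    d_low = update_theta_low(ca, state, params)
    state.theta_high += d_high
    state.theta_low += d_low
    np.clip(state.theta_high, 2.0 * params.theta_gap, None, out=state.theta_high)
    np.clip(
        state.theta_low, params.theta_gap / 10.0, state.theta_high - params.theta_gap,
        out=state.theta_low,
    )
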