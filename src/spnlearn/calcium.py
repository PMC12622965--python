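"""Calcium pools driving the plasticity rules.

Three separated pools are tracked, with no diffusion between sites:

* ``[Ca]_NMDA`` — per spine, driven by the NMDA receptor current; read by the
  LTP kernel.
* ``[Ca]_L-type`` — per spine, driven by the L-type share of the
  high-voltage-activated (HVA) calcium current; read by the LTD rule.
* ``[Ca]_v`` — per dendritic-shaft compartment, driven by all voltage-gated
  calcium currents; read by the inhibitory plasticity rule.

Every pool obeys the same scalar dynamics: linear influx from its source
current, a Michaelis-Menten extrusion pump, and first-order decay to
baseline.  The many voltage-gated channel types of the real cell are
collapsed into two Boltzmann-activated surrogate conductances, a low-voltage-
activated (LVA) one and an HVA one, of which a fixed fraction of the HVA
current is "L-type".

Absolute concentration scales are anchored by calibration
(:func:`calibrate_calcium`) to the plasticity thresholds: the initial LTP
kernel midpoint (0.02 mM) for the NMDA pool and the 70 nM LTD threshold for
the L-type pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CalciumPool",
    "PeakTracker",
    "VgccParams",
    "CalciumScales",
    "update_pool",
    "vgcc_activation",
    "vgcc_current",
    "calibrate_calcium",
    "CalibrationError",
]


@dataclass
class CalciumPool:
    """One calcium pool (mM) with pump extrusion and first-order decay."""

    source: str                    # "NMDA", "L-type" or "all-VGCC"
    influx_scale: float            # mM per nA*ms
    pump_vmax: float = 6e-4        # mM/ms
    pump_km: float = 3e-3          # mM
    decay_tau: float = 50.0        # ms
    baseline: float = 0.0          # mM
    concentration: float = 0.0

    def __post_init__(self):
        self.concentration = max(self.concentration, 0.0)


@dataclass
class PeakTracker:
    stimulus_onset: float = 0.0
    peak_since_onset: float = 0.0

    def reset(self, onset: float, value: float = 0.0):
        self.stimulus_onset = onset
        self.peak_since_onset = value

    def observe(self, value: float):
        if value > self.peak_since_onset:
            self.peak_since_onset = value


@dataclass
class VgccParams:
    """Boltzmann surrogates for the voltage-gated calcium channels.

    The LVA midpoint is >= 10 mV more negative than the HVA midpoint; the HVA
    slope is deliberately sharp so that sustained plateau depolarization
    (about -30 mV) opens the channels while subthreshold excursions do not —
    this is what keeps the silent-stimulus L-type calcium below the 70 nM LTD
    threshold.
    """

    lva_vhalf: float = -50.0   # mV
    lva_slope: float = 6.0     # mV
    lva_tau: float = 20.0      # ms
    hva_vhalf: float = -20.0   # mV
    hva_slope: float = 3.0     # mV
    hva_tau: float = 5.0       # ms
    e_ca: float = 30.0         # mV, surrogate ohmic reversal
    l_fraction: float = 0.5    # L-type share of the HVA current
    # absolute conductances (uS); small enough to be electrically negligible —
    # the channels are calcium sensors here, the influx scales set the mM units
    g_lva_spine: float = 1e-5
    g_hva_spine: float = 2e-5
    g_lva_shaft: float = 1e-5
    g_hva_shaft: float = 2e-5


@dataclass
class CalciumScales:
    """Influx scales (mM per nA*ms) and pool time constants."""

    scale_nmda: float = 1.0
    scale_ltype: float = 1.0
    scale_v: float = 1.0
    tau_nmda: float = 50.0
    tau_ltype: float = 80.0
    tau_v: float = 80.0
    baseline_v: float = 5e-5      # mM; spine pools represent evoked increments (baseline 0)
    # Michaelis-Menten pump: near-saturated for large (plateau) transients,
    # proportionally strong for small ones, sharpening the evoked contrast
    pump_vmax: float = 6e-4       # mM/ms
    pump_km: float = 3e-3         # mM
    nmda_ca_fraction: float = 0.1  # nominal calcium share of the NMDA conductance
    # stereotyped bAP-evoked calcium per somatic spike (mM per spike at the
    # soma end of a dendrite, decaying with distance).  These impulses carry
    # the spike-gated VGCC calcium of the back-propagating action potential
    # into the L-type and all-VGCC pools.  They are deliberately independent
    # of the influx scale factors: the plateau-driven and spike-driven
    # components of the LTD calcium would otherwise lose their contrast.
    bap_ca_ltype: float = 14e-3   # mM per spike
    bap_ca_v: float = 2e-4        # mM per spike
    bap_ca_lambda: float = 200.0  # um
    # calcium driving-force reversal for the NMDA calcium component; the net
    # NMDA current reverses at 0 mV but its calcium flux does not
    e_ca_nmda: float = 130.0      # mV
    # share of the adjacent extrasynaptic NMDA influx credited to a spine's
    # NMDA pool.  Keeping this well below 1 keeps the pool weight-dependent
    # (the synaptic component scales with w) and keeps the subthreshold
    # calcium within reach of the wide metaplasticity kernel (around 0.4x the
    # plateau level), which the sliding-threshold dynamics rely on
    extrasyn_ca_fraction: float = 0.10


def update_pool(pool: CalciumPool, influx_current: float, dt: float) -> float:
    """Advance a pool one step; returns the new concentration (mM).

    d[Ca]/dt = scale*I - vmax*[Ca]/([Ca]+km) - ([Ca]-baseline)/tau, floored at 0.
    """
    if not np.isfinite(influx_current):
        raise ValueError("non-finite calcium influx current")
    ca = pool.concentration
    dca = (
        pool.influx_scale * influx_current
        - pool.pump_vmax * ca / (ca + pool.pump_km)
        - (ca - pool.baseline) / pool.decay_tau
    )
    pool.concentration = max(ca + dt * dca, 0.0)
    return pool.concentration


def vgcc_activation(v, vhalf: float, slope: float):
    """Steady-state Boltzmann activation in [0, 1], increasing in voltage."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vhalf) / slope))


def vgcc_current(v, m_lva, m_hva, params: VgccParams, shaft: bool = True):
    """Inward-positive LVA/HVA calcium currents (nA) for given gating states."""
    v = np.asarray(v, dtype=float)
    g_l = params.g_lva_shaft if shaft else params.g_lva_spine
    g_h = params.g_hva_shaft if shaft else params.g_hva_spine
    i_lva = g_l * np.asarray(m_lva) * (params.e_ca - v)
    i_hva = g_h * np.asarray(m_hva) * (params.e_ca - v)
    return np.clip(i_lva, 0.0, None), np.clip(i_hva, 0.0, None)


class CalibrationError(RuntimeError):
    """Raised when no scale factors satisfy all calibration targets."""


def calibrate_calcium(
    model,
    theta_ltp0: float = 0.02,
    theta_ltd: float = 7e-5,
    target_ltype_peak: float = 0.031,
    target_cav_peak: float = 6e-3,
    cluster_size: int = 8,
    sub_cluster_size: int = 4,
    weight: float = 0.25,
    n_iter: int = 4,
) -> dict:
    """Anchor the calcium scales of ``model`` to the plasticity thresholds.

    Runs deterministic (noise-free) stimulus windows on a probe cluster and
    rescales the three influx factors so that:

    (i)   a spillover-triggering cluster (``cluster_size`` synapses at weight
          0.25) yields peak [Ca]_NMDA within [0.5, 2] x theta_ltp0;
    (ii)  a subthreshold cluster (``sub_cluster_size`` synapses) yields peak
          [Ca]_NMDA < 0.5 x theta_ltp0;
    (iii) a plateau plus somatic spike yields peak [Ca]_L-type above the LTD
          threshold while the silent subthreshold stimulus stays below it.

    The influx scales act linearly (the pump's nonlinearity is mild), so each
    factor is fixed by a short fixed-point iteration; the voltage dynamics set
    the triggered/subthreshold contrast, which no influx scale can repair —
    if the contrast is insufficient the calibration fails loudly.
    """
    report: dict = {"targets": {}, "factors": {}}

    probe_full = model.probe_cluster_window(cluster_size, weight, force_spike=False,
                                            full_stimulus=True)
    probe_sub = model.probe_cluster_window(sub_cluster_size, weight, force_spike=False)
    if not probe_full["spillover"]:
        raise CalibrationError("probe cluster did not trigger spillover")
    if probe_sub["spillover"]:
        raise CalibrationError("subthreshold probe cluster unexpectedly triggered spillover")

    sc = model.ca_scales

    def median_peak(key, n_active, full_stim, base_seed):
        vals = [
            model.probe_cluster_window(n_active, weight, force_spike=False,
                                       full_stimulus=full_stim,
                                       noise_seed=base_seed + 13 * k)[key]
            for k in range(3)
        ]
        return float(np.median(vals))

    # NMDA pool: anchored slightly below the kernel midpoint under
    # training-like conditions (triggered cluster, unspecific population,
    # noise, natural spiking).  Starting below the midpoint lets the
    # peak-driven downward kernel shift sweep the kernel through the observed
    # calcium, giving rewarded synapses a sustained potentiation phase.
    for _ in range(n_iter):
        med = median_peak("peak_ca_nmda", cluster_size, True, 777)
        if med <= 0:
            raise CalibrationError("no NMDA calcium in the triggered probe")
        sc.scale_nmda *= 0.8 * theta_ltp0 / med
        model.refresh_parameters()

    # L-type pool: plateau-plus-spiking stimulation anchored at the level
    # that makes the published LTD rate effective
    for _ in range(n_iter):
        med = median_peak("peak_ca_ltype", cluster_size, True, 555)
        if med <= 0:
            raise CalibrationError("no L-type calcium in the triggered probe")
        sc.scale_ltype *= target_ltype_peak / med
        model.refresh_parameters()

    # all-VGCC shaft pool for the inhibitory rule
    for _ in range(n_iter):
        med = median_peak("peak_ca_v", cluster_size, True, 333)
        if med <= sc.baseline_v:
            raise CalibrationError("no shaft VGCC calcium signal in the probe cluster")
        sc.scale_v *= target_cav_peak / med
        model.refresh_parameters()

    full = model.probe_cluster_window(cluster_size, weight, force_spike=False,
                                      full_stimulus=True)
    sub_ctx = model.probe_cluster_window(sub_cluster_size, weight, force_spike=False,
                                         full_stimulus=True)
    silent = model.probe_cluster_window(sub_cluster_size, weight, force_spike=False)

    checks = {
        "nmda_triggered_in_band": 0.5 * theta_ltp0 <= full["peak_ca_nmda"] <= 2.0 * theta_ltp0,
        "nmda_subthreshold_low": sub_ctx["peak_ca_nmda"] < 0.5 * theta_ltp0,
        "ltype_plateau_above_ltd": full["peak_ca_ltype"] > theta_ltd,
        "ltype_silent_below_ltd": silent["peak_ca_ltype"] < theta_ltd,
    }
    report["targets"] = {
        k: {"pass": bool(v)} for k, v in checks.items()
    }
    report["achieved"] = {
        "peak_ca_nmda_triggered": full["peak_ca_nmda"],
        "peak_ca_nmda_subthreshold": sub_ctx["peak_ca_nmda"],
        "peak_ca_ltype_plateau_spike": full["peak_ca_ltype"],
        "peak_ca_ltype_silent": silent["peak_ca_ltype"],
        "peak_ca_v_triggered": full["peak_ca_v"],
    }
    report["factors"] = {
        "scale_nmda": sc.scale_nmda,
        "scale_ltype": sc.scale_ltype,
        "scale_v": sc.scale_v,
    }
    if not all(checks.values()):
        failed = [k for k, v in checks.items() if not v]
        raise CalibrationError(
            f"calibration targets not satisfiable: {failed}; achieved {report['achieved']}"
        )
    model.calibrated = True
    model.calibration_report = report
    return report


def write_calibration_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
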