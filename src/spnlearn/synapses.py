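"""Saturating AMPA/NMDA synapses, glutamate spillover units, GABA synapses
and background noise.

Excitatory synapses sit on spines and carry co-scaled AMPA and NMDA
conductances: the weight ``w`` is the fraction of the maximal conductance and
multiplies both receptor types, so potentiation changes the total drive but
not the NMDA:AMPA ratio.  Cooperative activation is captured by glutamate
spillover: when the summed weight of co-activated synapses in a cluster (or,
in the distributed/branch mode, on a whole dendritic branch) reaches a
threshold of 2, a slow extrasynaptic NMDA conductance on the dendritic shaft
is activated once for that stimulus, producing the prolonged plateau
potential.

Gating uses a saturating dual-exponential scheme: a presynaptic spike sets
both the rise and decay state variables to 1 (full utilization), so the
normalized gating of any spike train is bounded by the single-spike peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExcitatorySynapse",
    "SpilloverUnit",
    "InhibitorySynapse",
    "NoiseProcess",
    "SynapseKinetics",
    "SaturatingGate",
    "mg_block",
    "nmda_current",
    "check_spillover",
    "generate_background_noise",
]

FEATURES = ("yellow", "red", "banana", "strawberry", "unspecific")

SPILLOVER_THRESHOLD = 2.0  # summed weight of co-active synapses


@dataclass
class SynapseKinetics:
    """Rise/decay time constants (ms) and maximal conductances (uS)."""

    tau_ampa_rise: float = 0.5
    tau_ampa_decay: float = 5.0
    tau_nmda_rise: float = 3.0
    tau_nmda_decay: float = 70.0
    tau_extrasyn_rise: float = 10.0    # slower glutamate clearance outside the cleft
    tau_extrasyn_decay: float = 160.0
    tau_gaba_rise: float = 1.0
    tau_gaba_decay: float = 12.0
    g_max_nmda: float = 2.5e-3         # uS; w = 0.25 -> 0.625 nS
    g_max_ampa: float = 2.0e-3         # uS; AMPA share of the co-scaled conductance
    g_max_extrasyn_nmda: float = 2.5e-3  # uS
    e_exc: float = 0.0                 # mV
    e_gaba: float = -60.0              # mV
    mg_conc: float = 1.0               # mM
    mg_k: float = 3.57                 # mM, Mg unbinding constant
    mg_slope: float = 0.062            # 1/mV


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalization so a unit event peaks at gating = 1."""
    if tau_rise >= tau_decay:
        raise ValueError("rise time constant must be shorter than decay")
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return 1.0 / peak


@dataclass
class SaturatingGate:
    """Reference implementation of the saturating dual-exponential gate.

    The simulation kernel replicates this update; this object is the
    single-synapse API used in tests and characterization.
    """

    tau_rise: float
    tau_decay: float
    r: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        self.norm = dual_exp_norm(self.tau_rise, self.tau_decay)

    def deliver_spike(self):
        """Full-utilization event: both states jump to saturation (1)."""
        self.r = 1.0
        self.d = 1.0

    def advance(self, dt: float):
        self.r *= math.exp(-dt / self.tau_rise)
        self.d *= math.exp(-dt / self.tau_decay)

    @property
    def value(self) -> float:
        return self.norm * (self.d - self.r)


@dataclass
class ExcitatorySynapse:
    spine: int                       # spine index (one spine per synapse)
    w: float                         # fraction of g_max, in [0, w_cap]
    feature: str = "unspecific"
    cluster: int | None = None       # spillover unit membership; None = not pooled
    g_max_ampa: float = 2.0e-3       # uS
    g_max_nmda: float = 2.5e-3       # uS

    def __post_init__(self):
        if not self.feature:
            raise ValueError("feature label must be a non-empty string")
        if self.w < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class SpilloverUnit:
    cluster: int
    shaft_compartment: int
    threshold: float = SPILLOVER_THRESHOLD
    g_max_extrasyn_nmda: float = 2.5e-3   # uS
    triggered_at: float | None = None


@dataclass
class InhibitorySynapse:
    shaft_compartment: int
    w_inh: float                     # uS
    feature: str = "unspecific"
    w_inh_max: float = 0.005         # uS
    reversal: float = -60.0          # mV

    def __post_init__(self):
        if not 0.0 <= self.w_inh <= self.w_inh_max:
            raise ValueError("inhibitory weight outside [0, w_inh_max]")


@dataclass
class NoiseProcess:
    """Aggregated background synapses: Poisson events per compartment.

    Each dendritic compartment carries one excitatory and one inhibitory
    non-saturating dual-exponential synapse whose event rate stands in for
    the many converging background inputs.
    """

    exc_rate: float = 6.0            # Hz per dendritic compartment
    inh_rate: float = 4.0            # Hz per dendritic compartment
    exc_weight: float = 0.12e-3      # uS per event
    inh_weight: float = 0.6e-3       # uS per event
    tau_exc_rise: float = 0.5
    tau_exc_decay: float = 4.0
    tau_inh_rise: float = 1.0
    tau_inh_decay: float = 12.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.exc_rate < 0 or self.inh_rate < 0:
            raise ValueError("noise rates must be non-negative")


def mg_block(v, mg_conc: float = 1.0, mg_k: float = 3.57, mg_slope: float = 0.062):
    """Fraction of NMDA conductance unblocked at voltage ``v`` (mV).

    Sigmoidal in voltage, ~0.5 near -20 mV at 1 mM Mg.
    """
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + (mg_conc / mg_k) * np.exp(-mg_slope * v))


def nmda_current(v, gating, w: float, g_max: float, e_rev: float = 0.0,
                 kin: SynapseKinetics | None = None):
    """NMDA current (nA): I = w * g_max * gating * B(V) * (V - E).

    Negative values are inward (depolarizing) with the convention that
    synaptic currents are reported as membrane currents.
    """
    kin = kin or SynapseKinetics()
    v = np.asarray(v, dtype=float)
    b = mg_block(v, kin.mg_conc, kin.mg_k, kin.mg_slope)
    return w * g_max * np.asarray(gating) * b * (v - e_rev)


def check_spillover(unit: SpilloverUnit, synapses: list[ExcitatorySynapse],
                    active_ids: list[int], t: float | None = None) -> bool:
    """Trigger test: summed weight of the unit's co-active synapses >= threshold.

    The comparison is inclusive: eight synapses at weight 0.25 sum to exactly
    2.0 and must trigger.  Triggering latches for the current stimulus.
    """
    members = {i for i, s in enumerate(synapses) if s.cluster == unit.cluster}
    unknown = set(active_ids) - set(range(len(synapses)))
    if unknown:
        raise KeyError(f"unknown synapse ids {sorted(unknown)}")
    total = sum(synapses[i].w for i in active_ids if i in members)
    if total >= unit.threshold - 1e-12:
        if unit.triggered_at is None:
            unit.triggered_at = t if t is not None else 0.0
        return True
    return False


def generate_background_noise(
    process: NoiseProcess,
    duration: float,
    n_compartments: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson event trains for the aggregated noise synapses.

    Returns ``(times_ms, compartment, is_inhibitory)`` sorted by time.
    Compartment 0 (the soma) receives no background synapses.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng(process.rng_seed)
    times, comps, kinds = [], [], []
    for rate, kind in ((process.exc_rate, 0), (process.inh_rate, 1)):
        if rate <= 0:
            continue
        lam = rate * duration * 1e-3
        for c in range(1, n_compartments):
            n = rng.poisson(lam)
            if n:
                times.append(rng.uniform(0.0, duration, size=n))
                comps.append(np.full(n, c, dtype=np.int64))
                kinds.append(np.full(n, kind, dtype=np.int64))
    if not times:
        return np.empty(0), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    t = np.concatenate(times)
    c = np.concatenate(comps)
    k = np.concatenate(kinds)
    order = np.argsort(t, kind="stable")
    return t[order], c[order], k[order]
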