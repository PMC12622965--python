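"""The nonlinear feature binding problem (NFBP): stimuli, feedback, training.

Four stimuli combine one color and one shape: red+strawberry and
yellow+banana are *relevant* (the neuron should spike), red+banana and
yellow+strawberry are *irrelevant* (it should stay silent).  Each block of 12
presentations contains every stimulus exactly three times in shuffled order.
A stimulus lasts 20 ms (one randomly timed spike per feature synapse);
feature-unspecific synapses are activated over 50 ms; inhibitory synapses of
the stimulus features within 100 ms.  The reward cue arrives 300 ms after
onset and lasts 50 ms: dopamine +1 for relevant stimuli if the neuron spiked,
-1 for irrelevant stimuli if it spiked, 0 otherwise (in the subthreshold
variant the cue is delivered regardless of spiking).  Learning is continuous:
there is no separate test phase.

Performance is the percentage of correct responses (spike on relevant,
silence on irrelevant) over a trailing window of 160 stimuli; the task counts
as solved when performance exceeds 87.5 % (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .model import SPNModel
from .plasticity_exc import ExcPlasticityParams, LtpKernelState, apply_excitatory_feedback
from .plasticity_inh import InhPlasticityParams, InhThresholdState, apply_inhibitory_update

__all__ = [
    "Stimulus",
    "TrainingProtocol",
    "ResponseRecord",
    "PerformanceTrace",
    "NFBP_STIMULI",
    "make_stimulus_sequence",
    "stimulus_events",
    "dopamine_feedback",
    "performance",
    "solved_criterion",
    "run_training",
    "extended_task_generator",
]

COLORS = ("red", "yellow")
SHAPES = ("strawberry", "banana")


@dataclass(frozen=True)
class Stimulus:
    features: frozenset
    relevant: bool

    @property
    def name(self) -> str:
        color = next(f for f in self.features if f in COLORS or f.startswith("color"))
        shape = next(f for f in self.features if f in SHAPES or f.startswith("shape"))
        return f"{color}+{shape}"


NFBP_STIMULI = (
    Stimulus(frozenset({"red", "strawberry"}), True),
    Stimulus(frozenset({"yellow", "banana"}), True),
    Stimulus(frozenset({"red", "banana"}), False),
    Stimulus(frozenset({"yellow", "strawberry"}), False),
)


@dataclass
class TrainingProtocol:
    n_stimuli: int = 960
    stimulus_duration: float = 20.0      # ms, feature synapses
    unspecific_window: float = 50.0      # ms, feature-unspecific synapses
    inhibitory_window: float = 100.0     # ms, inhibitory synapses
    reward_delay: float = 300.0          # ms after onset
    reward_duration: float = 50.0        # ms
    inter_stimulus_interval: float = 800.0  # ms
    block_size: int = 12
    subthreshold_mode: bool = False
    performance_window: int = 160
    rng_seed: int = 0

    @property
    def window_duration(self) -> float:
        return self.reward_delay + self.reward_duration

    def effective_n_stimuli(self) -> int:
        n = (self.n_stimuli // self.block_size) * self.block_size
        return n


@dataclass
class ResponseRecord:
    index: int
    stimulus: str
    relevant: bool
    spiked: bool
    dopamine: int
    correct: bool


@dataclass
class PerformanceTrace:
    """Running trailing-window performance, per stimulus presentation."""

    overall: np.ndarray                       # %, one value per stimulus
    per_type: dict                            # name -> (indices, correct flags)
    window: int

    def final(self) -> float:
        return float(self.overall[-1])


def make_stimulus_sequence(
    protocol: TrainingProtocol,
    stimuli: tuple = NFBP_STIMULI,
    rng: np.random.Generator | None = None,
) -> list[Stimulus]:
    """Concatenation of independently shuffled blocks, each holding every
    stimulus ``block_size / len(stimuli)`` times."""
    rng = rng if rng is not None else np.random.default_rng(protocol.rng_seed)
    if protocol.block_size % len(stimuli):
        raise ValueError("block size must be a multiple of the number of stimuli")
    reps = protocol.block_size // len(stimuli)
    n = protocol.effective_n_stimuli()
    seq: list[Stimulus] = []
    for _ in range(n // protocol.block_size):
        block = list(stimuli) * reps
        order = rng.permutation(len(block))
        seq.extend(block[i] for i in order)
    return seq


def stimulus_events(
    model: SPNModel,
    stimulus: Stimulus,
    protocol: TrainingProtocol,
    rng: np.random.Generator,
):
    """Presynaptic event times for one stimulus window (onset at t = 0).

    Every excitatory synapse whose feature is part of the stimulus receives
    exactly one spike in [0, 20] ms; unspecific synapses one spike in
    [0, 50] ms; inhibitory synapses of the stimulus features one spike in
    [0, 100] ms.
    """
    exc_t, exc_i = [], []
    for i, syn in enumerate(model.exc_synapses):
        if syn.feature in stimulus.features:
            exc_t.append(rng.uniform(0.0, protocol.stimulus_duration))
            exc_i.append(i)
        elif syn.feature == "unspecific":
            exc_t.append(rng.uniform(0.0, protocol.unspecific_window))
            exc_i.append(i)
    inh_t, inh_i = [], []
    for j, syn in enumerate(model.inh_synapses):
        if syn.feature in stimulus.features:
            inh_t.append(rng.uniform(0.0, protocol.inhibitory_window))
            inh_i.append(j)
    return (
        (np.asarray(exc_t), np.asarray(exc_i, dtype=np.int64)),
        (np.asarray(inh_t), np.asarray(inh_i, dtype=np.int64)),
    )


def dopamine_feedback(spiked: bool, stimulus: Stimulus, protocol: TrainingProtocol) -> int:
    """Phasic dopamine level delivered at onset + 300 ms for 50 ms."""
    if protocol.subthreshold_mode:
        return 1 if stimulus.relevant else -1
    if not spiked:
        return 0
    return 1 if stimulus.relevant else -1


def performance(records: list[ResponseRecord], window: int = 160) -> float:
    """Percent correct over the last `window` records."""
    if not records:
        raise ValueError("no response records")
    window = min(window, len(records))
    tail = records[-window:]
    return 100.0 * float(np.mean([r.correct for r in tail]))


def solved_criterion(perf: float) -> bool:
    """The NFBP counts as solved when performance strictly exceeds 87.5 %."""
    return perf > 87.5


@dataclass
class TrainingResult:
    records: list[ResponseRecord]
    trace: PerformanceTrace
    weights: np.ndarray                 # final excitatory weights
    theta_ltp: np.ndarray
    weights_inh: np.ndarray
    theta_inh: tuple | None
    weight_history: np.ndarray          # (n_samples, n_exc)
    weight_history_index: np.ndarray
    plasticity_log: pd.DataFrame
    solved: bool

    @property
    def final_performance(self) -> float:
        return self.trace.final()


def run_training(
    model: SPNModel,
    protocol: TrainingProtocol,
    exc_params: ExcPlasticityParams | None = None,
    inh_params: InhPlasticityParams | None = None,
    plasticity_exc: bool = True,
    plasticity_inh: bool = True,
    seed: int = 0,
    stimuli: tuple = NFBP_STIMULI,
    forced_dopamine: int | None = None,
    history_every: int = 24,
    log_plasticity: bool = False,
) -> TrainingResult:
    """Train the model on the (continuous) NFBP protocol.

    Each stimulus: reset peak trackers, simulate the 350 ms response window
    with background noise, decide the spike over [onset, onset + 300 ms],
    deliver dopamine, update eligible excitatory synapses (at reward time) and
    every inhibitory synapse (each stimulus, dopamine-independent).  The long
    800 ms inter-stimulus interval returns all state variables to baseline,
    which the loop implements by restarting each window from the resting
    state.  Fully reproducible for a given seed.
    """
    exc_params = exc_params or ExcPlasticityParams()
    inh_params = inh_params or InhPlasticityParams()
    ss = np.random.SeedSequence(seed)
    seq_rng, ev_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    protocol = replace(protocol, rng_seed=seed)
    sequence = make_stimulus_sequence(protocol, stimuli=stimuli, rng=seq_rng)

    n_exc = len(model.exc_synapses)
    n_inh = len(model.inh_synapses)
    kernel_state = LtpKernelState.initial(n_exc, exc_params)
    inh_state = InhThresholdState.initial(n_inh, inh_params)

    records: list[ResponseRecord] = []
    perf_curve = np.zeros(len(sequence))
    correct_flags = np.zeros(len(sequence), dtype=bool)
    history, history_idx = [], []
    log_rows = []

    exc_features = np.array([s.feature for s in model.exc_synapses])
    inh_features = np.array([s.feature for s in model.inh_synapses])

    for idx, stim in enumerate(sequence):
        exc_ev, inh_ev = stimulus_events(model, stim, protocol, ev_rng)
        res = model.run_window(
            protocol.window_duration,
            exc_events=exc_ev,
            inh_events=inh_ev,
            noise_rng=noise_rng,
            decision_window=protocol.reward_delay,
        )
        spiked = res.n_spikes_decision > 0
        if forced_dopamine is not None:
            dopamine = forced_dopamine
        else:
            dopamine = dopamine_feedback(spiked, stim, protocol)

        eligible = np.isin(exc_features, list(stim.features) + ["unspecific"])
        if plasticity_exc and dopamine != 0:
            apply_excitatory_feedback(
                model.w, kernel_state, res.peak_ca_nmda, res.peak_ca_ltype,
                eligible, dopamine, exc_params,
            )
        if plasticity_inh and n_inh:
            active_inh = np.isin(inh_features, list(stim.features))
            apply_inhibitory_update(
                model.w_inh, inh_state, res.peak_ca_v[model.inh_comp],
                active_inh, inh_params,
            )

        correct = (stim.relevant and spiked) or (not stim.relevant and not spiked)
        correct_flags[idx] = correct
        lo = max(0, idx + 1 - protocol.performance_window)
        perf_curve[idx] = 100.0 * float(np.mean(correct_flags[lo: idx + 1]))
        records.append(
            ResponseRecord(idx, stim.name, stim.relevant, spiked, dopamine, correct)
        )
        if idx % history_every == 0 or idx == len(sequence) - 1:
            history.append(model.w.copy())
            history_idx.append(idx)
        if log_plasticity:
            for s in range(n_exc):
                if eligible[s]:
                    log_rows.append(
                        (idx, s, dopamine, res.peak_ca_nmda[s], res.peak_ca_ltype[s],
                         model.w[s], kernel_state.theta_ltp[s])
                    )

    per_type: dict = {}
    for stim in stimuli:
        sel = np.array([r.stimulus == stim.name for r in records])
        per_type[stim.name] = (np.nonzero(sel)[0], correct_flags[sel])
    trace = PerformanceTrace(perf_curve, per_type, protocol.performance_window)
    log = pd.DataFrame(
        log_rows,
        columns=["stimulus", "synapse", "dopamine", "ca_nmda_peak", "ca_ltype_peak",
                 "w", "theta_ltp"],
    )
    final = performance(records, protocol.performance_window)
    return TrainingResult(
        records=records,
        trace=trace,
        weights=model.w.copy(),
        theta_ltp=kernel_state.theta_ltp.copy(),
        weights_inh=model.w_inh.copy(),
        theta_inh=(inh_state.theta_low.copy(), inh_state.theta_high.copy()) if n_inh else None,
        weight_history=np.array(history),
        weight_history_index=np.array(history_idx),
        plasticity_log=log,
        solved=solved_criterion(final),
    )


def extended_task_generator(n_values_per_feature: int = 3):
    """Stimulus sets for the extended tasks: n x n color/shape combinations.

    ``n = 2`` is the standard NFBP; ``n = 3`` gives 9 combinations with one
    nonlinear (conjunction-defined) relevant pair; ``n = 5`` gives 25 with two.
    Relevant sets follow the same recipe as the NFBP: matched color/shape
    pairs are rewarded, everything else is not.
    """
    if n_values_per_feature not in (2, 3, 5):
        raise ValueError("supported sizes: 2, 3, 5")
    if n_values_per_feature == 2:
        return list(NFBP_STIMULI)
    colors = [f"color{i}" for i in range(n_values_per_feature)]
    shapes = [f"shape{i}" for i in range(n_values_per_feature)]
    n_nonlinear = 1 if n_values_per_feature == 3 else 2
    relevant_pairs = {(colors[i], shapes[i]) for i in range(n_nonlinear + 1)}
    stimuli = []
    for c, s in product(colors, shapes):
        stimuli.append(Stimulus(frozenset({c, s}), (c, s) in relevant_pairs))
    return stimuli
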