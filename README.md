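# spnlearn

Can a single neuron solve a task that is linearly non-separable? `spnlearn`
studies this question for the **nonlinear feature binding problem (NFBP)** in
a reduced model of a **direct-pathway striatal projection neuron (dSPN)**:
four stimuli combine a color and a shape (red/yellow × strawberry/banana),
the neuron must spike for *red+strawberry* and *yellow+banana* and stay
silent for the two complementary combinations — a discrimination no weighted
sum of single-feature inputs can make.

The package implements, end to end:

* a compartmental surrogate of a dSPN (soma + tapering dendrites, leak + KIR
  + slow A-type potassium, explicit spines) with **NMDA-dependent dendritic
  plateau potentials**: when the summed weight of co-activated synapses in a
  cluster reaches a spillover threshold of 2, a slow extrasynaptic NMDA
  conductance produces a prolonged, regenerative local depolarization;
* three local **calcium pools** per site ([Ca]_NMDA, [Ca]_L-type, [Ca]_v),
  each with pump extrusion and first-order decay, calibrated against the
  plasticity thresholds;
* the **calcium- and dopamine-gated excitatory learning rule**

  σ(Ca, θ, β) = 1 / (1 + e^(−β(Ca−θ)))

  * LTP (dopamine peak): Δw = η_ltp · σ′([Ca]_NMDA, θ_ltp, β_ltp) — a
    bell-shaped kernel over peak NMDA calcium;
  * LTD (dopamine pause): Δw = −η_ltd · [Ca]_L · σ([Ca]_L, θ_ltd, β_ltd) · w
    with a fixed 70 nM threshold;
  * **metaplasticity**: θ_ltp slides down after peaks and up — four times
    faster — after pauses, Δθ_ltp = ∓η_s · σ′([Ca]_NMDA, θ_ltp, β_mp),
    stabilizing weights and routing LTP away from pause-entangled synapses;
* a **BCM-style inhibitory rule**: Ω(Ca) = a·σ(Ca, θ_low, β_inh) +
  b·σ(Ca, θ_high, β_inh) with sliding thresholds tracking the local
  voltage-gated calcium, no dopamine dependence;
* the **training protocol**: 960 block-shuffled stimuli, 20 ms stimulation,
  dopamine feedback at +300 ms for 50 ms (+1 relevant∧spiked, −1
  irrelevant∧spiked, 0 otherwise), 800 ms inter-stimulus interval,
  continuous learning, performance = % correct over the trailing 160
  stimuli, solved ⇔ performance > 87.5 %;
* the experiment suites: plateau-onset characterization, the 31 clustered
  input configurations, cluster-distance and distributed-placement sweeps,
  the linear control task, and the no-metaplasticity control.

See `docs/methods.md` for the model details, calibration procedure and the
design decisions.

## Worked example

Characterize the plateau mechanism (smallest co-active cluster that triggers
glutamate spillover, per synaptic weight):

```
$ spnlearn characterize --seed 0 --out results
weight 0.2: plateau onset at 10 co-active synapses
weight 0.25: plateau onset at 8 co-active synapses
weight 0.4: plateau onset at 5 co-active synapses
```

Eight baseline synapses (w = 0.25) sum to the spillover threshold of 2.0;
strengthened synapses (0.4) need five, weakened ones (0.2) need ten — the
cooperativity that lets one dendrite encode a feature conjunction.

Train the standard clustered setup (three features per host dendrite) with
excitatory plasticity and metaplasticity:

```
$ spnlearn train --seed 1 --out results
final performance: 95.0% (solved: True)
results in results/performance.csv
```

The neuron starts by spiking for all four stimuli (feature-unspecific drive),
then the rule strengthens the clusters of the relevant conjunctions, weakens
the dendrite's irrelevant feature and the unspecific inputs, and the running
performance climbs from 50 % to above the 87.5 % solved criterion.

Other entry points: `spnlearn sweep-configs` (all 31 feature-to-dendrite
assignments), `spnlearn sweep-distance` (performance vs. cluster location,
quadratic fit), `spnlearn distributed` (random placements with branch-wide
spillover), `spnlearn linear-task` (single rewarded stimulus). Each accepts
`--seed`, `--scale {desk,full}`, `--inhibition {on,off}` and writes CSV/JSON
results with a reproducibility manifest.

Everything is also available as a library:

```python
from spnlearn import build_clustered_setup, run_training
from spnlearn.experiments import default_protocol, default_exc_params

model = build_clustered_setup(seed=0)          # builds + calibrates calcium
result = run_training(model, default_protocol(),
                      exc_params=default_exc_params(),
                      plasticity_inh=False, seed=1)
print(result.final_performance, result.solved)  # 95.0 True
```

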