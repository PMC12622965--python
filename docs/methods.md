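# Methods

`spnlearn` implements a calcium- and dopamine-gated synaptic learning rule in
a reduced compartmental surrogate of a direct-pathway striatal projection
neuron (dSPN), and trains that neuron on the nonlinear feature binding
problem (NFBP). This note describes the model, the calibration that anchors
its calcium scales, the design choices made where the design was genuinely
open, and what the synthetic experiments do and do not show.

## The electrical surrogate

The cell is a soma (15 µm cylinder) plus 12 unbranched dendrites of 200 µm
(ten 20 µm segments, diameter tapering 0.8 → 0.64 µm), with three membrane
conductances everywhere:

* passive leak (0.10 mS/cm², reversal −85 mV),
* an inward-rectifier (KIR-like) potassium conductance (0.15 mS/cm²,
  half-activation −82 mV, closing on depolarization) — the source of the very
  hyperpolarized SPN resting potential (≈ −87 mV here, within the −90..−80 mV
  band) and of the increased input resistance in depolarized states,
* a slow A-type (KAs-like) potassium conductance (0.2 mS/cm², opening around
  −55 mV). This opposes the KIR-closure positive feedback and stabilizes the
  global "up state": without it, the background input could latch the whole
  tree into a depolarized state. Per compartment it is ~0.05 nS — far too
  small to oppose a clustered NMDA plateau.

Integration is operator-split exponential Euler: each compartment relaxes
exponentially toward the reversal implied by its instantaneous conductances
(frozen over the step), then the constant axial coupling is applied
implicitly with a prefactorized O(n) tree solve. The scheme is
unconditionally stable for the allowed dt range (0.01–0.5 ms); training runs
use dt = 0.2 ms, characterization 0.1 ms. With KIR off, its steady states
match the exact linear cable solution (tested to 0.1 %).

Spines are a neck resistance (500 MΩ) plus a head node treated as being in
instantaneous equilibrium with the shaft (its time constant is microseconds),
so the head voltage is algebraic and the spine couples to the shaft as a
series conductance.

Somatic spikes are threshold/reset events: threshold −60 mV, reset −68 mV,
refractory 25 ms (the soma is held at the reset during the refractory
period). The −60 mV value is the spike-initiation-zone criterion appropriate
for a soma with no sodium current: the passive up state must be able to reach
it. (`detect_somatic_spikes`, the trace-analysis utility, keeps −40 mV as its
default threshold for analyzing recorded voltage.) Each spike also injects a
weak, stereotyped back-propagating conductance transient into the dendrites
and — more importantly — a distance-decaying calcium impulse into the L-type
and all-VGCC pools (below).

## Synapses and the plateau mechanism

Excitatory synapses are saturating AMPA (2 nS max, τ 0.5/5 ms) plus NMDA
(2.5 nS max, τ 3/70 ms, standard exponential Mg block with ~half unblock at
−20 mV) on spines; one presynaptic spike drives the gating to saturation, so
repeated spikes cannot exceed the single-spike peak. The weight w (fraction
of the maximal conductance, initial 0.25 ± 0.05) multiplies AMPA and NMDA
together.

Glutamate spillover is an event rule: when the summed weight of co-activated
synapses in a cluster (or, in the distributed setup, on a whole dendritic
branch) reaches 2.0 — inclusive, so eight synapses at 0.25 trigger — a slow
extrasynaptic NMDA conductance (τ 10/300 ms) activates once for that
stimulus on the host shaft. Its magnitude is threshold-linear in the
co-active weight, `g_ex · (40 + Σw − 2)` with g_ex = 2.5 nS: a large base
pool at the trigger point plus an excess term, so potentiation enhances
spillover and the plateau is graded in the learned weights. The base is
large deliberately: the surrogate soma is passive, and at the end of
learning — when the feature-unspecific input has weakened — the plateau
alone must carry the soma from the background level (≈ −72 mV) across the
spike threshold. With this choice a triggered stimulus spikes the cell
reliably and a non-triggering one essentially never does, at any level of
feature-unspecific drive; the spiking decision inherits the trigger's
cooperativity, which is the computational point of the plateau.

Feature-unspecific synapses (108; 144 with inhibition) are placed at
proximal/mid sites (10–70 µm): their job is somatic excitability early in
training, and low-impedance proximal positions deliver that without igniting
branch plateaus. Background noise is an aggregated excitatory (6 Hz,
0.12 nS) and inhibitory (4 Hz, 0.6 nS) Poisson synapse per dendritic
compartment, holding the soma near −75 mV with no spontaneous spikes.

GABA synapses (reversal −60 mV, τ 1/12 ms, weight ≤ 0.005 µS) sit on shafts
near the clusters (clustered setup) or scattered (distributed setup).

## Calcium pools

Three pools, no diffusion between sites, all with linear influx, a
Michaelis–Menten pump (vmax 6·10⁻⁴ mM/ms, Km 3·10⁻³ mM — proportionally
strong for small transients, saturated for large ones) and first-order decay:

* **[Ca]_NMDA** (per spine, τ 50 ms): driven by the spine's NMDA conductance
  times the *calcium* driving force (reversal +130 mV), not the net current —
  the net current reverses at 0 mV and its voltage dependence cancels the
  Mg-unblock contrast the learning rule needs. Once a spine's unit has
  triggered and the spine was co-activated, the adjacent extrasynaptic
  receptors contribute a share (0.10, scaled by the spine's weight) of their
  influx to this pool; that couples the pool to the plateau's full duration
  rather than the synapse's own ~70 ms glutamate transient, and it is what
  produces the discontinuous calcium jump at the trigger size.
* **[Ca]_L-type** (per spine, τ 80 ms): the L-type half of a sharp
  high-voltage-activated Boltzmann surrogate (half-activation −20 mV, slope
  3 mV) plus a stereotyped spike-triggered impulse (0.014 mM per somatic
  spike at the soma end, length constant 200 µm) standing in for bAP-evoked
  VGCC influx. This pool is therefore effectively spike-gated: silent
  stimuli leave it orders of magnitude below the 70 nM LTD threshold.
* **[Ca]_v** (per shaft compartment, τ 80 ms, baseline 50 nM): all
  voltage-gated sources (low- plus high-threshold surrogates) plus a smaller
  spike impulse; read by the inhibitory rule at its synapse's compartment.

The VGCC conductances themselves are electrically negligible (tens of pS);
they are calcium sensors, and the absolute mM scales are set by calibration.

### Calibration

`calibrate_calcium` anchors the three influx scales on the assembled model
with deterministic training-like probes (the largest cluster's synapses at
weight 0.25, one spike each across the 20 ms window, the unspecific
population active, background noise from a fixed seed, natural spiking):

1. peak [Ca]_NMDA of a triggered cluster ≈ 0.8 × θ_LTP0 (0.02 mM). The
   anchor sits slightly *below* the kernel midpoint so that the peak-driven
   downward kernel shift sweeps the kernel through the observed calcium,
   giving consistently rewarded synapses a sustained potentiation phase;
2. peak [Ca]_L-type of the same plateau-plus-spiking probe = 0.031 mM, the
   level at which the published LTD rate produces the published per-event
   weight decrements;
3. peak [Ca]_v at the cluster shaft = 1.5·10⁻³ mM, above the initial
   inhibitory thresholds and well above baseline.

It then verifies, and fails loudly otherwise: triggered [Ca]_NMDA within
[0.5, 2] × θ_LTP0; a four-synapse subthreshold probe below 0.5 × θ_LTP0 (it
lands near 0.4 × — within reach of the wide metaplasticity kernel, which the
sliding-threshold dynamics require); plateau-plus-spike [Ca]_L-type above
the 70 nM LTD threshold and the silent probe below it.

## The excitatory learning rule

Per stimulus, at the reward cue (300 ms after onset, 50 ms long), for every
synapse that received a presynaptic spike during that stimulus:

* dopamine +1 (relevant stimulus, neuron spiked): Δw = η_LTP ·
  σ′([Ca]_NMDA^peak; θ_LTP, β_LTP) · T_LTP, the bell-shaped kernel;
* dopamine −1 (irrelevant stimulus, neuron spiked): Δw = −η_LTD ·
  [Ca]_L^peak · σ([Ca]_L^peak; 70 nM, β_LTD) · w · 50 ms;
* dopamine 0: nothing, bit-identically.

θ_LTP (per synapse, initial 0.02 mM) shifts by ∓η_s · σ′([Ca]_NMDA^peak;
θ_LTP, β_mp) · 50 ms — down after peaks, up four times faster after pauses —
with the wide kernel (β_mp = 334 mM⁻¹) sharing the midpoint. All rate
constants are the published ones; two operational choices resolve their
dimensional inconsistency (the LTP rate is given per µS·mM·ms, which cannot
integrate to a dimensionless weight change over the 50 ms cue without
producing single-event jumps of ~0.19):

* the LTP pathway integrates over an equivalent window T_LTP = 15 ms per
  cue, which reproduces the published per-event increment scale while LTD
  and both kernel shifts integrate over the full 50 ms cue;
* a single global rate factor (2.0 in the default experiments) multiplies
  the two weight rates — not the kernel-shift rates, which at accelerated
  rates overshoot into a frozen state the bell-shaped kernel cannot leave —
  compensating for the 960-stimulus protocol relative to the longest
  published runs.

The weight ceiling is w_cap = 0.38: five synapses of one fully potentiated
feature sum to 1.9, just below the spillover threshold, so a single feature
can never trigger a plateau by itself — discrimination then requires a
conjunction, which is the task's definition of nonlinearity. (The published
weight trajectories stay below ≈ 0.6 for the same functional reason.)

Stabilization is calcium-based: [Ca]_NMDA grows superlinearly with w (the
synaptic and extrasynaptic shares both scale with it), so a potentiated
synapse's calcium slides out of the narrow LTP kernel and potentiation shuts
itself off; the kernel midpoint meanwhile tracks reward history, denying LTP
to synapses entangled with dopamine pauses.

## The inhibitory learning rule

Dopamine-independent and per-stimulus: every inhibitory synapse is updated
from the peak [Ca]_v at its compartment through the two-sigmoid Ω function
with sliding thresholds θ_inh,low < θ_inh,high (initial 10⁻⁴ and 5·10⁻⁴ mM;
a 10⁻⁵ mM guard keeps them ordered, clipping θ_low — their behavior at
crossing is otherwise unspecified). Active synapses potentiate between the
thresholds and depress above θ_high; inactive synapses mirror the signs; the
soft-bound factor w(w_max − w) pins the ends of the range. θ_high tracks the
largest observed calcium, θ_low settles below it (offset c aligning the two
update curves' zero crossing). All constants are the published Table values;
the same global rate factor and 50 ms event window apply.

## Task protocol

Four stimuli (red+strawberry and yellow+banana relevant; red+banana and
yellow+strawberry irrelevant), 960 presentations in reshuffled blocks of 12
(three of each per block). Per stimulus: one spike per feature synapse in
[0, 20] ms, per unspecific synapse in [0, 50] ms, per stimulated inhibitory
synapse in [0, 100] ms; spike decision over [0, 300] ms; reward cue at
300–350 ms; 800 ms inter-stimulus interval. The interval returns every state
variable to within 1 % of baseline (verified by simulation), so the training
loop restarts each window from the resting state. Performance is the percent
of correct responses over the trailing 160 stimuli; solved means
strictly > 87.5 %. Learning is continuous — no separate test phase.

## What the experiments show, and don't

* **Clustered learning (the headline experiment).** With pre-clustered
  features on two host dendrites at 90 µm, excitatory plasticity alone
  solves the NFBP for nearly all configurations in which neither dendrite
  carries all four features (measured mean ≈ 94 % over the 18 such
  configurations, 17/18 solved, at the default seed). The learned state has
  the relevant pair weights near the ceiling, the dendrite's irrelevant
  feature near zero, and the unspecific population weakened.
* **Controls.** Disabling metaplasticity leaves the kernel unable to
  separate reward histories and the standard configuration fails the solved
  criterion; disabling plasticity leaves weights bit-identical.
* **Linear task.** With randomly distributed synapses and a single rewarded
  stimulus the network reaches high (~80–90 %) performance; it converges
  more slowly than the clustered task because non-clustered synapses start
  below the LTP kernel and must be recruited by the kernel's descent.
* **Distance sweep.** Performance versus cluster distance shows an interior
  optimum (quadratic fit), with proximal clusters penalized by the somatic
  current sink and the most distal by weaker somatic coupling.
* **Distributed setup.** Branch-wide spillover pooling gives random
  placements a chance of storing one or both relevant stimuli on individual
  branches; with inhibitory plasticity the contrast between stored and
  competing features increases.

The generator emulates the study's stimulus statistics, background activity
and placement rules; it does not emulate real corticostriatal input
statistics (correlations, rate codes), receptor kinetics beyond
dual-exponential saturation, calcium buffering or diffusion, or the full
dSPN channel repertoire. Passing tests therefore demonstrate the internal
consistency of the learning mechanism under the stated conditions, not a
quantitative fit to biological data.

## Numerical choices and degenerate inputs

dt ∈ [0.01, 0.5] ms enforced; event times are binned to steps. Sigmoids are
clipped at |x| = 700 before exponentiation. Calcium pools are floored at
zero and reject non-finite influx. The spillover latch is reset at each
stimulus onset. Non-finite voltages abort the window with the offending
compartment id. Empty synapse sets, empty traces and zero-rate noise are
all valid degenerate inputs. Reproducibility: every stochastic component
draws from a seeded generator; identical (seed, configuration) pairs replay
bit-identically, including across the numba-compiled and pure-Python kernel
paths (same arithmetic).

## Known limitations

The spike mechanism has no afterhyperpolarization dynamics beyond the fixed
reset, so firing during strong plateaus is refractory-limited at 40 Hz. The
threshold-linear spillover recruitment is a surrogate for receptor-pool
recruitment that the underlying biophysics only motivates qualitatively.
The 18-configuration result is reported for one placement seed per
configuration; seed-to-seed spread of individual configurations is a few
percentage points. The extended 9- and 25-combination tasks are provided as
generators but their accuracies are not part of the validated surface.
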