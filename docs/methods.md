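# Methods

## The problem

Given a set of target ("reference") spike trains — binary rasters
`S ∈ {0,1}^{T×N}` with a 3 ms timestep — the package tunes the synaptic
weight matrix of a recurrent leaky integrate-and-fire (LIF) network so that,
driven by fixed external currents, the network reproduces those trains.  The
learning rule, Pre-Synaptic Pool Modification (PSPM), needs no gradients and
no knowledge of post-synaptic potentials: it only assumes that the causal
history of a spike is summarized by which neurons fired in the recent past.
Around the rule sit the pieces needed to evaluate it: the simulators, a
dynamic-programming spike matcher, van Rossum-style distances, inter-spike
interval (ISI) comparison, and neuronal-avalanche criticality analysis.

## Network models

**LIF.** Subthreshold membrane dynamics follow
`τ dV_i/dt = −V_i + R_m I_i(t) + Σ_j W_ij s_j(t)`, integrated by forward
Euler with step `dt`.  When the updated potential reaches `V_th` the neuron
emits a spike and resets to 0 mV.  Parameters (defaults): τ = 30 ms,
R_m = 100 MΩ, V_th = 30 mV, dt = 3 ms, N = 400, 20 % of neurons inhibitory.
Weights are stored in volts and carry the sign of their presynaptic neuron
(Dale-like constraint); voltages are handled in mV internally.  Design
choices the governing equations leave open:

* the synaptic sum at step t uses spikes from step t−1, which makes the
  update order-independent (an effective one-step axonal delay);
* no autapses: `W_ii = 0` always — a neuron should not re-excite itself one
  step after reset;
* `V_i(0) = 0` (the reset value); no refractory period; recorded voltage
  traces are post-reset, hence always below threshold.

External currents are i.i.d. Gaussian, N(2.5×10⁻¹⁰ A, 1×10⁻¹⁰ A) per
neuron per step.  Under this integrator a zero-weight network fires at
≈1.3 Hz, and synaptic input dominates once weights are at their mV scale —
the drive perturbs, the recurrence decides.

**Initial weight configurations.** Four named (reference, naive) magnitude
laws, all in volts: `uniform` U[0, 5 mV] for both; `gaussian` |N(0.4 mV,
0.4 mV)| with negative draws redrawn (a proper left-truncated normal, mean
≈0.515 mV); `sparse` U[0, 5 mV] with exactly ⌊N²/2⌋ off-diagonal naive
entries zeroed; `naive-half-max` U[0, 5 mV] reference against U[0, 2.5 mV]
naive.  Reference and naive networks of a trial share one inhibitory
assignment so that mirrored updates respect the same sign structure.

**PIF.** The probabilistic integrate-and-fire network is a discrete-time
branching process: neuron i fires at t+1 with probability
`min(1, Σ_j W_ij s_j(t) + I_i(t))`, realized by comparison with a fresh
U[0,1) threshold.  Connectivity is Bernoulli(p = 0.1), weights U[0, 0.02],
all excitatory, and the matrix is divided by its largest-magnitude
eigenvalue so the spectral radius — the branching parameter — is exactly 1.
Drive is Poisson(1) × 0.001 per neuron per step.

A dynamical caveat that matters for interpretation: at spectral radius 1 a
branching process conserves the expected size of each ongoing cascade, so
with sustained drive (≈0.4 seeded spikes/step network-wide) the expected
activity has no stable low-activity fixed point; it drifts upward until the
`min(1,·)` saturation and weight heterogeneity arrest it.  At N = 400 the
stationary state sits near 0.46 spikes/step/neuron, and the summed-activity
threshold excursions are correspondingly few and long (≈350 per 50,000
steps).  Reported low-rate, many-avalanche statistics for this architecture
correspond to an effective branching ratio well below 1 (≈0.7 reproduces
them); with the normalization pinned at 1 they are not reachable, and the
avalanche statistics this package reports for the critical PIF are the ones
the model as defined actually produces.

## Spike matching

Per neuron, reference spike times `t^(r)_1..n` and observed times
`t^(o)_1..m` are aligned by a dynamic program over the cost table
`Λ ∈ R^{(n+1)×(m+1)}`: pairing spikes k,l costs `d_kl = |t^(r)_k −
t^(o)_l|`, leaving a spike unpaired costs `a_cap` (default 15 steps ≈
45 ms), and the recursion takes the cheapest of pair / skip-reference /
skip-observed / skip-both (the last is dominated but kept as an explicit
branch).  Backtracking from Λ[n,m] with a fixed tie-break precedence
(pair, skip-ref, skip-obs, skip-both) yields a bit-reproducible optimal
monotone pairing plus the two unpaired lists.  Note the recursion happily
pairs spikes up to 2·a_cap apart (pairing beats double-unpairing whenever
d < 2a_cap); a strict post-filter that demotes such pairs is available but
off by default, since the recursion is the definition.  Rows of the table
are vectorized by folding the in-row dependence into a running minimum of
`candidate[l] − l·a_cap`.

## PSPM learning rules

Each epoch, against fixed inputs:

1. simulate the current network → observed raster O;
2. match every neuron's observed spikes to its reference spikes (all
   pairings computed from the epoch's raster before any weight changes);
3. **local updates** — for each unpaired reference spike at time t of
   neuron i ("missing"), every presynaptic j ≠ i with an observed spike in
   the closed window [t − z, t] (z = 10 steps) gets `W_ij += δ`, δ ~
   U[0, δ_max] drawn independently per synapse; for each unpaired observed
   spike ("extra"), the same with subtraction.  Neurons are processed in
   index order, missing before extra.  Weights never change sign: a
   crossing update clips the weight to exactly 0;
4. **homeostatic update** — with x total reference spikes and y total
   observed spikes, every off-diagonal weight receives an independent draw
   from U[0, (x − y)·h] volts (a negative interval when the network
   overshoots), then sign clipping.  The rule is self-gating: it vanishes
   as y → x;
5. **control mirroring** — every local delta is also applied to a control
   copy of the naive network at an independently chosen uniformly random
   off-diagonal synapse (batched per epoch: deltas accumulate on their
   targets, then one clipping pass, so the result is order-independent).
   The control receives its own homeostatic draws from the same (x − y)
   interval.  The control thus gets identical update counts and magnitudes
   but uninformative placement — the contrast isolates what placement buys.

**Update magnitudes.** Defaults are δ_max = 1×10⁻⁴ V and h = 1×10⁻⁸ V per
unit spike-count mismatch, keeping a 10⁴ ratio between the per-synapse
local draw and the homeostatic unit.  The scales are set by dimensional
analysis: with weights of a few mV and a dt/τ = 0.1 coupling of synaptic
input into the membrane, the updates accumulated on a presynaptic pool over
~10² epochs must reach the mV voltage-margin scale for an induced or
eliminated spike to be dynamically possible; a per-draw cap near 0.1 mV
achieves that, while values orders of magnitude smaller leave the dynamics
bit-identical across a whole training run.  Both knobs are exposed in
`LearningConfig`.

## Spike-train similarity measures

Binary trains are convolved with an unnormalized symmetric Gaussian kernel
`K(t) = exp(−t²/2σ²)`, σ = 5√2 steps (≈21 ms), truncated at ±5σ with
zero padding — a van Rossum-style filtering with tolerance on both sides of
a spike.  Two distances follow: the pairwise distance
`D_P(S,R) = Σ_i Σ_t [a(s_i) − a(r_i)]²` (neuron-by-neuron) and the
aggregate distance `D_A(S,R) = Σ_t [A(S) − A(R)]²` on network-summed
signals (invariant to neuron relabeling).  All integrals are unit-weight
sums over timesteps; distances are reported in these natural units.
Because filtering is linear, `D_P` is computed as one convolution of the
raster difference.

ISI distributions pool per-neuron inter-spike intervals network-wide and
are compared by the ℓ2 distance between histograms on shared fixed-width
bins (default 3 steps ≈ 9 ms — the bin width is a free choice, exposed in
configs).  Spike-count statistics use the population variance over neurons.
Weight-matrix disagreement is the component-wise sum of squared differences
(squared Frobenius norm).

## Avalanche analysis

Summed activity `F(t) = Σ_i s_i(t)` is thresholded at the 20th percentile
of all T values (linear interpolation, zeros included); an avalanche is a
maximal run of steps with F strictly above threshold, its duration the run
length and its size the total spikes inside.  Runs truncated by the raster
edges are kept by default (a flag drops them).  Sizes and durations are fit
by discrete power-law maximum likelihood, `P(x) = x^−γ / ζ(γ, x_min)` with
x_min = 1 (Hurwitz-zeta normalization, bounded scalar optimization;
standard errors from the observed Fisher information).  The crackling-noise
relation is then checked two ways: β predicted as (α − 1)/(τ − 1) from the
fitted exponents, and β observed as the OLS slope of log mean-size-per-
duration against log duration (mean sizes are reported with a positive
scaling exponent, the standard convention).  Their absolute difference is
the criticality consistency score; both a failure to fit (degenerate or
scant samples) and a large gap mark non-critical activity.

## Experiment runner and seeding

The learning study repeats, per trial: draw sign mask, reference and naive
weights, and inputs; simulate the reference; train with PSPM; score naive,
optimized, and control rasters against the reference with D_P, D_A, ISI ℓ2,
spike-count statistics and weight error; aggregate mean ± SD over trials.
The criticality-transfer study builds a critical PIF, simulates a long
reference raster, splits it into equal segments, trains one all-excitatory
LIF (naive weights U[0, 10⁻³] V, Gaussian currents) per segment, and runs
the criticality report on the reference and on the concatenated naive,
optimized and control rasters.  Every random draw descends from the master
seed via `SeedSequence([master_seed, trial, stream])`, so results are fully
reproducible and adding trials never perturbs existing ones.

## Problem sizes used by the test and acceptance runs

The full-scale studies (N = 400, T = 10⁴–5×10⁴, 150 epochs, 30 trials) are
the configured defaults.  The distributed checks run the same pipelines at
desk scale, chosen as the package's own verification sizes: the learning
orderings at N = 20, T = 1000, 50 epochs, 10 trials (where the dynamics are
fluctuation-driven rather than saturated, and one study takes seconds); the
PIF pipeline at its full printed size (N = 400, T = 50,000, five seeds);
and the criticality transfer at N = 100, T = 4000 over two segments, 10
epochs, five seeds.

## What the synthetic conditions do and do not show

All data is generated by the package's own models, so the tests
demonstrate internal consistency of the method under its stated generative
conditions — recoverability of spike timing, the optimized-vs-control
contrast, and the avalanche machinery's calibration on known power laws.
They do not demonstrate robustness to anything real recordings add:
unmodeled neuron classes, non-stationary drive, measurement noise, or
subsampled populations.  Two scale effects deserve emphasis: (i) weight
non-identifiability — optimized weights drifting no closer to the reference
despite matching spike trains — is a large-N phenomenon; at N = 20 the
presynaptic pools are informative enough that weight error actually
*improves* slightly (≈2 %) while D_P halves, so "spike-train fit without
weight recovery" should be read as "weight recovery is not commensurate
with spike-train fit"; (ii) the critical-PIF avalanche regime depends
qualitatively on the interplay of drive and branching ratio discussed
above, not just on the spectral normalization.

## Known limitations

* LIF only (no Hodgkin–Huxley/Izhikevich/SRM), current-based synapses, the
  one-step delay convention, no refractory period.
* Matching is per-neuron; no joint multi-neuron alignment, no
  Victor–Purpura metric proper, no differentiable relaxations.
* Power-law fitting fixes x_min = 1 (configurable) rather than selecting it
  by KS minimization; exponents for heavy, saturated activity distributions
  are therefore descriptive rather than model-selected.
* Training cost is dominated by per-event pool updates and per-neuron
  matching (O(n·m) per neuron per epoch); dense rasters make epochs
  quadratic in the per-neuron spike count.
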