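# Model and methods

`spikewm` simulates a 500-unit spiking network whose population activity is
decoded into the wheel speeds of a virtual two-wheeled agent, and exercises
it through six working-memory protocols (learning/recall, incremental
learning, task switching, interference, washout-then-interference, and weak
distraction).  This note records the model equations, the package's own
numerical and design choices, and what the shipped defaults do and do not
demonstrate.

## Units and state

Internally everything is in mV, ms, pA, nS and pF (pF·mV/ms = pA).
Parameters printed in nA (stimulus amplitudes, the spike-triggered adaptation
increment) are converted at the configuration boundary.  Unit indices are
0-based in memory and 1-based in every file and report.

The state of the network is: membrane potential `V_i` and adaptation current
`w_i` per unit; release probability `u_j` and neurotransmitter availability
`x_j` per *presynaptic* unit (shared across that unit's efferents, as the
per-unit subscripts of the release equations indicate); postsynaptic current
`I_syn_i`; the signed weight matrix `J[i, j]` (synapse j → i) with its binary
connectivity mask `C`; and each unit's two most recent somatic spike times.

## Membrane dynamics (aEIF)

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - w + I_syn + I_ext
    τ_w dw/dt = a_w (V - E_L) - w

with C_m = 281 pF, g_L = 30 nS, E_L = -70.6 mV, V_T = -50.4 mV, Δ_T = 2 mV,
τ_w = 144 ms, a_w = 4 nS, b_w = 0.0805 nA, V_peak = 20 mV.  A spike is
registered when V > V_T after the update; V resets to E_L (V_reset = E_L),
w jumps by b_w, and V_peak is recorded cosmetically (never integrated).
There is no refractory period.

Integration is forward Euler at dt = 0.1 ms (configurable).  The exponential
term's argument is clamped at +20 to avoid overflow between threshold
crossing and reset; this cannot affect subthreshold behaviour.  Convergence
under dt halving, agreement of the rest point with a root-finding oracle, and
agreement of the subthreshold response with the matrix-exponential solution
of the linearised two-variable system are all asserted by the test suite.
Non-finite state aborts the run with a diagnostic naming dt.

## Short-term plasticity

Between spikes, `u` relaxes to the baseline release probability U = 0.80 with
τ_f = 100 ms and `x` to 1 with τ_d = 900 ms — applied as exact exponential
updates, not Euler.  On a presynaptic spike (somatic or background):

    u → u + U (1 - u);   release = u_new · x;   x → (1 - u_new) x

The transmitted fraction uses the post-jump `u` and the pre-decrement `x`;
the update order matters and is fixed here because the governing equations
leave it ambiguous (the availability decrement -u·x is consistent with
updating `u` first).  With these constants the synapse is
depression-dominated: sustained firing collapses `x` and therefore the
per-spike current.

## Transmission

A spike of presynaptic unit j injects `g_scale · J[i, j] · release` pA into
every connected target i, after which the postsynaptic current decays as
`I_syn ← I_syn · exp(-dt/τ_syn)` with τ_syn = 5 ms.  The total-efficacy sum
over presynaptic units is bookkeeping: each individual spike contributes its
own synapse's efficacy, and the current equation's sum over spikes assembles
the total.  `g_scale` (the dimensionless-efficacy → current conversion) has
no printed value; the default of 1000 pA per unit efficacy makes a handful of
coincident excitatory spikes suprathreshold from rest (one initial-strength
excitatory spike from a rested synapse peaks at ≈ 624 pA ≈ 11 mV of
depolarisation; the rheobase from rest is ≈ 550 pA).  Somatic spikes are
delivered on the following integration step (one-step synaptic delay);
background spikes are delivered within their step.

## Spike-timing-dependent plasticity

The pair rule on the signed weight, with Δt = t_post - t_pre:

    ΔJ = +λ₊ (1-J)^μ exp(-Δt/τ₊)        Δt > 0   (potentiation)
    ΔJ = -λ₋ α sgn(J)|J|^μ exp(Δt/τ₋)   Δt ≤ 0   (depression)

λ₊ = 5·10⁻⁵, λ₋ = 25·10⁻⁵, τ₊ = 20 ms, τ₋ = 50 ms, α = 2, μ = 1.  The
multiplicative factors soft-bound excitatory weights to [0, 1].  For J < 0
both branches are non-negative, so inhibitory efficacies drift monotonically
toward zero and beyond under sustained pairing — this sign violation is a
documented property of the model and is reported
(`connection_stats.dale_violations`), not prevented.  The signed power
`sgn(J)|J|^μ` keeps that property for any μ; at the default μ = 1 it is
exactly α·J.

**Pairing convention.**  Nearest neighbour: only the partner's most recent
spike *strictly before* the current one is used.  For simultaneous spikers
and for a unit pairing with itself, this is the penultimate spike.  The
strict-precedence reading is what lets structural plasticity create
self-connections (a unit's consecutive spikes form a causal pair); pairing
with the partner's literal latest spike would make every self-lag zero and
self-connections impossible, contradicting the model's documented behaviour.

**Evaluation modes.**  Two modes are implemented and cross-checked:

* `event` — the rule is applied once per spike: every spike updates, as
  postsynaptic, all its incoming synapses (potentiation branch) and, as
  presynaptic, all its outgoing synapses (depression branch).
* `continuous` (default) — the rule is applied at *every integration step*
  to every ordered pair whose spike-time difference is defined.  Since Δt
  only changes when an endpoint spikes, this weights each branch by its
  residence time: a pair that fires in a consistent pre-before-post order
  spends almost its whole inter-spike cycle in the potentiation branch and
  only the short causal lag in the depression branch.

The continuous mode is the default because it is the only reading under
which evoked activity strengthens synapses at these constants.  The printed
rates are depression-dominant (αλ₋/λ₊ = 10, τ₋ > τ₊): under per-spike
(event) application, any stationary co-firing statistic drives an excitatory
weight to the fixed point λ₊E₊/(λ₊E₊ + αλ₋E₋) ≲ 0.1 — *below* the initial
0.65, so a cue could never imprint a memory, and the per-pairing magnitudes
(≈ 5·10⁻⁵) are far too small to matter over tens of seconds anyway.  Under
continuous (residence-time) evaluation, causally ordered firing — exactly
what strong recurrent drive produces inside a stimulated bump — potentiates
on a seconds timescale, uncorrelated low-rate firing depresses, and the six
behavioural protocols come out as observed.  The learning rates are
per-evaluation quantities, so in continuous mode the effective learning
speed is tied to dt; all shipped results use dt = 0.1 ms.

**Structural plasticity.**  All ordered pairs are evaluated whether or not a
synapse exists; an update that actually moves a zero weight creates the
connection (`C[i,j] ← 1`, weight growing from 0).  Depression of an exactly
zero weight does nothing and creates nothing.  Connectivity is therefore
non-decreasing and, under ongoing stimulation, approaches full density
including the diagonal (self-connections) and sign-violating
inhibitory-origin synapses.  `allow_self_connections` (default on) can
disable diagonal growth for ablations.  Weights are clamped to [-1, 1] as a
safety net; the multiplicative rule keeps the defaults inside bounds on its
own.

## Background input

Each presynaptic unit carries an independent homogeneous Poisson train at
10 Hz, generated once per run from the run seed and then *frozen*: the same
realization drives evoked and spontaneous phases (the stronger reading of a
constant spatiotemporal noise pattern; the seed is exposed for the
alternative).  Background spikes drive the unit's STP variables and deliver
synaptic current through its current weights, but by default do not update
the spike-timing pairing times (`background_drives_stdp`, default off), so
long-term learning remains driven by somatic activity.

## Sensory input

The external current is a bimodal mixture of Gaussians on the unit-index
ring:

    I_ext(i) = scale · [R_b + R_p G(i; i_pref, σ) + R_n G(i; i_anti, σ)]

with R_b = 0.5, R_p = 2.5, R_n = 1.0 nA, σ = 35, and G a unit-height
Gaussian using ring (modulo-N) distance.  The second centre sits half the
ring away: indices are treated modulo N, which is the only placement
consistent with both peaks always falling inside 1..N (literally, the second
centre of the clockwise configuration would land outside the index range).
The clockwise configuration centres the higher peak on unit N/4 (125), the
counter-clockwise one on 3N/4 (375); the two are exact images under the
half-ring swap and have identical means, so only peak placement encodes the
cue.  OFF is exactly zero.  The distraction protocol scales the whole vector
by 1/3.

## Embodiment

Spike counts are taken in consecutive non-overlapping 40 ms bins, half-open
and anchored at t = 0.  Units 1–250 drive the left wheel and 251–500 the
right wheel — the unique assignment under which a bump at unit 125 speeds up
the left wheel and yields clockwise rotation.  Wheel speed is
`gain × count` (gain 0.5 mm/s per spike, wheelbase 48 mm; both cosmetic —
any monotone linear map preserves every qualitative result) held constant
within the bin; the planar pose advances by the exact constant-speed arc of
differential-drive kinematics.  Pose integration is exactly reversible,
which the tests exploit.

## Protocols and verdicts

The original experiments were paced by live keypresses; here they are fixed
event schedules.  Default durations: cue 20 s, recall 10 s, washout 60 s
(submission protocol), interferer 4 s, incremental cues 5/10/20 s — chosen
once so that each protocol completes in about a minute of simulated time on
a desk machine.  Verdicts are defined relative to the configured schedule,
over the last 25% of each phase (onset transients excluded; fraction
configurable), using the subpopulation-dominance readout: the side with the
strictly larger spike count, or NONE when the counts differ by at most 5% of
their total.

* exp1 — recall dominance equals the cued side.
* exp2 — recall margins non-decreasing across lengthening cues
  (Kendall τ ≥ 0; a non-strict trend because short-cue margins are noisy).
* exp3 — every recall matches the most recent configuration.
* exp4 — the cue side still dominates after a brief opposite interferer.
* exp5 — gated: the washout window must first reach a tie (otherwise the
  verdict is *inconclusive*, distinct from fail); then the interferer side
  must dominate the final recall.
* exp6 — the cue side dominates both before and after an equal-duration
  opposite distractor at one-third intensity.

Robustness is quantified over three fixed seeds (41, 42, 43); the acceptance
suite requires each criterion on at least two of three.  All randomness in a
run (network wiring, E/I identity, background) derives from the single run
seed.

## Engines and numerical implementation

Two engines share one step semantics (STP decay → event delivery → current
update → Euler membrane step → spikers' STP jumps → STDP → recording):

* a plain-numpy engine, where continuous STDP is the literal full-matrix
  per-step update — the readable brute-force reference, practical for small
  networks;
* a numba engine for production runs.  In continuous mode the per-step
  update of a pair is a geometric recursion with a factor fixed between
  endpoint spikes, so it is applied lazily in closed form
  (`(1-J) ← (1-J)(1-λ₊k)ⁿ`, `J ← J(1-αλ₋k)ⁿ`) whenever a pair's lag
  changes or its weight is observed.  A pair's last-applied step is
  reconstructed from two per-unit stamps (`max(row_stamp[i], col_stamp[j])`),
  the per-lag window factors and their logarithms are precomputed on the
  dt grid, and lags beyond 38 window time constants are skipped — there the
  per-step factor rounds to 1 in double precision, so the reference
  recursion is a no-op as well.  The closed form requires μ = 1 (the default);
  other exponents fall back to the numpy engine.

The test suite asserts engine equivalence on identical inputs: bit-identical
spikes and weights in event mode, and 1e-9-level agreement in continuous
mode (the closed form differs from step-wise accumulation only by float
rounding).  Runs are bitwise deterministic given (config, seed), and
splitting a run into segments does not change it.

## What the shipped conditions show — and what they do not

The battery runs the full 500-unit network at the printed constants, with
the frozen-Poisson background as the only noise source.  At these defaults
the acceptance suite finds the network firmly in the *palimpsest* regime:
single and incremental learning/recall (exp1, exp2), task switching (exp3)
and overwrite-after-washout (exp5) hold on a majority of seeds, but
resistance to a brief full-intensity interferer (exp4) and to a prolonged
one-third-intensity distractor (exp6) does not — measured post-interference
margins show the later input dominant from the first second.  The reason is
structural: under per-step (residence-time) evaluation, the interfering
input learns at exactly the per-second rate the cue did, while the cue's
trace has been eroded by depression throughout the preceding recall
(spontaneous bump rates of 10–18 Hz keep the depression branch active), so
a later suprathreshold input always wins.  Resistance requires forgetting
several-fold slower than fresh learning — a regime set chiefly by the
efficacy-to-current scale through the spontaneous rates it produces, which
we deliberately do not retune; the two criteria are reported as failing
rather than adjusted into passing.

Passing protocols show that the mechanism — depression-dominated STP plus
residence-time-weighted multiplicative STDP over a sparse random network —
stores, refines and overwrites a cued bump, and that the decoded motor
behaviour tracks the network state.  The battery does not
show robustness to heterogeneous cellular parameters, conduction delays,
structured (correlated) noise, sensor noise or physical wheel dynamics:
units are identical, delays are one integration step, the background is
spatially independent, and the agent is kinematic.  The washout duration
needed in exp5 depends on the spontaneous rate and would shift under a
different background level.

## Known limitations

* Continuous-mode learning speed scales with 1/dt (per-evaluation rates);
  comparisons across dt values are not meaningful without rescaling λ±.
* Structural plasticity densifies the network quickly under strong drive;
  long (many-minute) stimulated runs drift toward a fully connected,
  Dale-violating network, with rising global excitability — inherited from
  the model, not guarded against.
* The spike-buffer guard aborts runs whose mean network rate exceeds
  400 Hz (`max_mean_rate_hz`), which signals runaway excitation under
  non-default parameters.
* Inhibitory weights share the single multiplicative rule, so inhibition
  weakens wherever pre and post fire together; there is no homeostasis.
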