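# Methods

## Generative model

Each source is a three-population neural mass in the David–Friston layout:
spiny stellate cells (granular layer, the target of forward and stimulus
input), pyramidal cells, and inhibitory interneurons. Every synaptic
connection applies second-order kinetics

    v̈ = (H/τ) s − 2 v̇/τ − v/τ²,

with excitatory gain H_e = 4 mV, inhibitory gain H_i = 32 mV and time
constants τ_e = 8 ms, τ_i = 16 ms. These canonical kinetics are written
with τ in seconds; the implementation keeps the user-facing time axis in
milliseconds and carries the resulting 1/1000 factor inside the lumped
drive constant, so the DC gain of one excitatory synapse is
H_e·τ_e[s] ≈ 0.032 mV per unit firing. Without that factor the
γ₁γ₂ stellate–pyramidal loop gain exceeds unity and the resting state is
unstable.

States per source: 9 (three populations × potential/current pairs plus the
pyramidal depolarization v₉ = v_exc − v_inh that is read out and fed to the
inter-source sigmoid). v₉ never enters any state equation, so the system
Jacobian has one structurally zero eigenvalue per source; all other modes
decay at rest.

Firing is the centered sigmoid S(v) = expit(r(v−η)) − expit(−rη) with
r = 0.56 /mV and η = 6 mV, so S(0) = 0 and the resting point is exactly
zero. Intrinsic gains are γ = 128·(1, 0.8, 0.25, 0.25). Population
targeting of extrinsic afferents: forward → spiny stellate; backward and
lateral → pyramidal and inhibitory; the stimulus (a Gaussian bump, onset
60 ms, width 16 ms) → spiny stellate of the input sources.

### Operating-regime calibration

The centered sigmoid's slope at rest is S′(0) ≈ 0.018 /mV, an order of
magnitude below its peak slope at threshold. Inter-source transmission is
therefore efficient only when afferent drive reaches several mV. The
extrinsic coupling prior means (free choices of this package; they are
pure gain constants in a.u.) are calibrated once so that the default
two-source network operates in that regime: F = 2048, B = 1024, L = 256,
U = 512 put the driven stellate population at ~8 mV, the primary source's
pyramidal output near 3 mV and the secondary source near 60% of the
primary. Rest remains asymptotically stable (all dynamical eigenvalue real
parts < 0). Free parameters are log-scalings of these means, with prior
variances 1/16 (extrinsic and input), 1/32 (condition modulations) and
1/128 (intrinsic deviations), so positivity is structural.

## Integrator

Local linearization per sample: with J = ∂f/∂x at the current state, the
update is x⁺ = x + (e^{ΔtJ} − I)J⁻¹f augmented with the input-rate term
Δt²φ₂(ΔtJ)(∂f/∂u)u̇ (exponential Rosenbrock–Euler). Both terms come from a
single augmented matrix exponential, which is exact where J is singular and
reduces to the plain update for constant input; without the input-rate term
the scheme degrades to first order for a time-varying stimulus. Because
Δv₉ = Δv_exc − Δv_inh holds exactly under the matrix exponential, the
integrator advances the nonsingular 8-states-per-source reduced system and
propagates v₉ by that identity — arithmetically identical to the
pseudo-inverse update on the full Jacobian, but cheaper and better
conditioned. Measured accuracy against a tolerance-1e-10 adaptive
Runge–Kutta reference: ~4.5e-4 relative max-abs error at Δt = 1 ms over a
500 ms window, converging at second order. Non-finite states abort with
the offending time index.

## Response Jacobian and its parallel decomposition

∂h/∂θ uses one-sided forward differences with step 1e-4 on the log-scale
parameters: N+1 integrations per EM iteration, the base response computed
once and shared. Each column is an independent task; tasks are laid out on
an abstract fabric descriptor (n_SM, resident blocks per SM, block capacity
1024, warp width 32) by one of three arrangements:

- `thread`: fill a block to capacity before opening the next;
- `block`: one task per block;
- `blockX`: strided round-robin over exactly X = n_SM × resident-limit
  blocks, spilling to a fresh set of X blocks when all are full.

The deterministic cost model — blocks execute in index order in waves of at
most X; a block of k tasks lasts ⌈k/warp⌉ units; the makespan is the sum of
per-wave maxima — is this package's own construction. It reproduces the
step pattern of probe cost versus block count (steps at multiples of X,
which is how `detect_concurrency_limit` finds X without reading the
descriptor) and the dominance of `blockX` over both naive arrangements for
every task count in 1–4096. Wall-clock timings are recorded by the
benchmark harness for information only; no test asserts them. The
thread-pool backend runs the same per-task arithmetic as the serial path,
so parallel and serial Jacobians agree exactly, and the worker count or
arrangement cannot change an inversion's trajectory.

## Inversion

Variational Laplace with diagonal-component precision models
Π(λ) = Σᵢ exp(λᵢ)Qᵢ (global identity by default; per-channel blocks
available). E-step: Gauss–Newton with curvature Jᵀ Π J + Σ₀⁻¹ on the free
subspace (zero prior variance freezes a parameter), Levenberg-style step
halving (max 8) until the free energy does not decrease; a numerically
singular curvature receives a ridge of 1e-8·tr(P)/N. M-step: Fisher-scoring
ReML on λ with the posterior-uncertainty trace term, λ clipped to ±32, each
inner step backtracked against F. An EM iteration is accepted only if it
does not lower F — recomputing J at the new expansion point can shave the
Occam term by a fraction of a nat near convergence, and such iterations are
reverted — so the recorded F trace is non-decreasing by construction.
Convergence: ΔF < 0.01 nats on two consecutive iterations, cap 128
iterations. EM starts deterministically at the prior mean; everything is
double precision.

For a linear generative map the first E-step lands on the conjugate
posterior mean exactly and F at the mode equals the analytic log marginal
likelihood, which the tests exploit as closed-form oracles.

## Model selection

Log evidence per subject and model is the converged free energy.
Fixed-effects group comparison sums log evidences over subjects and
softmaxes the sums (max-subtracted for stability); probabilities are
invariant to common shifts and sum to one.

## Synthetic data

The generator produces noiseless responses through the observation model
and adds Gaussian sensor noise calibrated on the trial-averaged scale:
per-trial variance n_trials · max(h²)/SNR, so the peak-signal-to-noise
power ratio of the averaged response equals the requested SNR regardless of
trial count. Defaults mirror common evoked-response acquisition: 250 Hz
sampling, 0–900 ms peristimulus window, SNR 10. Data-length scaling tiles
the epoch and truncates (sample k equals sample k mod n of the source
epoch); complexity scaling enables connections in a fixed order (forward,
backward, lateral, modulations, per-source intrinsic deviations) and tops
up with duplicated-prior intrinsic padding parameters, so any target
complexity at or above the base model is reachable exactly.

What the generator does *not* emulate: realistic lead fields (columns are
seeded unit-norm Gaussian vectors, not head-model topographies), trial-level
artifacts and non-Gaussian noise, spatially and temporally correlated
sensor noise, and inter-subject variability beyond lead field and noise
realization. Passing recovery tests therefore demonstrates correctness of
the estimator under the model's own assumptions (no model mismatch), not
performance on empirical EEG.

## Study sizes

The recovery study inverts a two-source forward+backward network
(true log-scalings 0.4, −0.3, 0.2) from 32 channels × 226 samples at
SNR 10; posterior standard deviations are ≈0.08, and the maximum absolute
error across the three couplings is ≈0.08–0.11 for typical seeds. The group
study uses 10 subjects × 3 candidate models at a reduced 0–400 ms window
(101 samples), which keeps one replication near ten seconds while leaving
the generating model's evidence margin at hundreds of nats; the
model-recovery criterion (winner with P > 0.99) held in 10/10 seeded
replications in our runs.

## Known limitations

- Three-population sources only; the four-population canonical microcircuit
  is out of scope (population targeting is centralized so a variant could
  be added).
- No conduction delays: the dynamics are a plain ODE system.
- Precision components must be diagonal in the flattened data basis.
- The fabric model ignores register/shared-memory occupancy limits, memory
  bank conflicts and host-device transfer costs; it is a scheduling
  abstraction, not a hardware simulator.
- Wall-clock mode of `detect_concurrency_limit` is best-effort and
  host-dependent; only the simulated mode is asserted in tests.
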