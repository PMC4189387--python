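# Methods

## The membrane model

All simulators share one deterministic backbone: the classical
Hodgkin-Huxley membrane

    C dV/dt = I − g̅_Na·x_Na·(V − V_Na) − g̅_K·x_K·(V − V_K) − g_L·(V − V_L)

with squid-axon constants (C = 1 μF/cm², g̅_K = 36, g̅_Na = 120,
g_L = 0.3 mS/cm²) and the six voltage-dependent gate rates α_x(V),
β_x(V) in the modern voltage convention (rest ≈ −65 mV; V_Na = 50,
V_K = −77, V_L = −54.4 mV).  α_m and α_n have removable singularities
(V = −40 and −55 mV); both the vectorized and the compiled scalar rate
functions switch to a series branch there, so the analytic limit is
returned exactly and the functions are continuous to < 1e−8.

The open fractions x_K, x_Na differ by model: n⁴ and m³h
(deterministic, oscillator model), the conducting-state fractions n₄
and s₇ (channel-state models).  A patch of area A μm² carries
N_K = round(18·A) potassium and N_Na = round(60·A) sodium channels; all
channel noise scales as A^(−1/2).  Area is the single noise knob: the
generator's default A = 400 μm² (N_K = 7200, N_Na = 24000) and the
default drive I = 6.0 μA/cm² are the reference operating point used
throughout, in the middle of the bistable window.

## Deterministic analysis

The gating equations pin m, h, n to their steady-state curves at a
fixed point, so fixed points reduce to a scalar root of the current
balance in V (Brent's method, |residual| < 1e−10 enforced).  The 4×4
Jacobian is assembled analytically from the rate derivatives
(cross-checked against central differences in the tests); over
I = 0–12 μA/cm² its spectrum is one complex pair −λ ± iω and two real
negative eigenvalues.  λ(I) crosses zero at the subcritical Hopf
bifurcation, located by Brent bisection on [6, 12] to 1e−3 (I₁ ≈ 9.78).
The cycle-onset current I_v ≈ 6.27 is found by bisecting, to 0.02
resolution, the classifier "does spiking persist in the final 1000 ms
of a 1000 ms transient + 2000 ms observation run started from a
spike-upstroke state harvested at I = 10".  The windows were chosen so
the slowest linear decay (|λ| ≈ 0.1/ms near the middle of the range)
has relaxed by many e-folds; the classification is verified
step-size-independent.  Deterministic integration is fixed-step RK4
(dt = 0.01 ms default, numba-compiled).

## The exact Markov chain (Micro)

Channel counts are integers over 5 potassium states (number of open
n-gates) and 8 sodium states (open m-gates × h-gate).  The 28 directed
edge propensities are (count in source state) × (gate multiplicity ×
rate).  Event times are exponential in the total propensity R;
between events the voltage advances by Euler substeps ≤ dt (0.005 ms)
with counts frozen.  Because the rates depend on V, R can go stale
during a long waiting time: if it drifts by more than 5% (relative) the
pending event is abandoned and redrawn from the current state — the
exponential law is memoryless, so this is exact to first order in the
drift.  The firing edge is chosen with probabilities proportional to
the propensities at the post-waiting voltage.  Channel totals are
checked after every event; a violation is an internal error, not a
recoverable condition.  Under voltage clamp the loop reduces to pure
Gillespie and accumulates time-weighted occupancies, which must match
the closed-form product-binomial stationary law (gates are independent
at fixed V) — this, plus conservation, is the exactness check.

Cost scales with R ≈ (channels) × (summed rates): about 10⁵ events per
simulated ms at A = 400.  ISI-distribution statistics for the Micro
model at the reference point are therefore a long-run computation by
design; the desk-scale suite validates the chain through its stationary
law, conservation, and the large-area limit (mean firing period at
A = 2000, I = 10 against the deterministic limit-cycle period, within
2% plus the Monte-Carlo error of the run).

## The 13-SDE shared-edge-noise Langevin model

One SDE per channel-state fraction.  Drift: net deterministic flux over
the incident edges.  Noise: one Gaussian increment per undirected edge,
with standard deviation sqrt((flux_fwd + flux_bwd)/N)·sqrt(dt),
entering the two incident state equations with opposite signs — 4 draws
for the potassium chain, 10 for the sodium chain, and each chain's
increments cancel exactly in every realization, so sums are conserved
without projection.  This is the diffusion approximation of the channel
Markov chain for density-dependent populations (error O(log N / N)).

Integration is Euler-Maruyama at dt = 0.005 ms with the boundary
protocol applied in this order each step: (1) update the 13 fractions;
(2) if any potassium fraction went negative, redraw that chain's 4
noises (up to 100 times, then abort with advice to reduce dt); any
negative sodium fraction is reset to zero; (3) renormalize each chain
to sum 1; (4) only then advance V by Euler using g_K = g̅_K·n₄,
g_Na = g̅_Na·s₇.  All noise amplitudes are evaluated at start-of-step
(Itô) fractions, which are non-negative by construction, so the square
roots are always defined.  The redraw re-samples all four potassium
edge noises rather than only the offending one; this choice is recorded
in the run manifest.

## The 7-SDE oscillator Langevin model

Gating SDEs for n, m, h with noise variances
(α(1−x)+βx)/(4N_K), /(3N_Na), /N_Na respectively (the
fluctuation-dissipation form: diffusion = drift with signs made
positive), clamped to [0, 1] after each step.  Two stochastic harmonic
oscillator pairs with unit-time-constant dynamics

    τ q̇ = p,   τ ṗ = −γ p − ω²(α(1−x)+βx) q + ξ,
    Var(ξ_K) = γ_K T_K (α_n(1−n)+β_n n),  Var(ξ_Na) = γ_Na T_Na (α_m(1−m)+β_m m)

with γ_K = γ_Na = 10, ω²_K = 150, ω²_Na = 200, T_K = 400, T_Na = 800,
modulate the conducting fractions through
ψ_K = n⁴ + √(n⁴(1−n⁴)/N_K)·q_K and
ψ_Na = m³h + √(m³(1−m³)/N_Na)·h·q_Na.  Two transcription choices were
genuinely open and are resolved as follows: the oscillator variable
inside ψ_K is q_K (each oscillator pairs with its own ion species), and
the state powers are n⁴ and m³ of the single gating variables.  The
oscillator time constant τ has no published value in our source; it is
a dimensional bookkeeping constant, defaulted to 1 ms and exposed in
`SimConfig.tau`.  Oscillators start at rest (q = p = 0).  With five
Gaussian draws per step (vs 14) this is the fastest simulator, roughly
3× the 13-SDE model's throughput here.

## Simulation protocol

Every trajectory starts at the deterministic fixed point for its I with
channel variables at the clamped stationary law (exact multinomial
counts for Micro, expected fractions for the SDEs) and a
per-trajectory seed derived from (master seed, model, trajectory
index) via `numpy.random.SeedSequence` spawn keys — results are
independent of execution order.  Spikes are downward crossings of
0 mV (well above the subthreshold range, which stays below ≈ −50 mV),
linearly interpolated between samples; the first spike of each
trajectory is discarded as transient, and ISIs are pooled across the
ensemble.  Runs stop on a duration or on a pooled-ISI target, with a
hard time budget (500 ms per requested spike by default) whose
exhaustion is an error, never a silent truncation.

## ISI feature extraction

Histograms are equal-width (1 ms default) from zero, normalized to unit
mass.  Features:

* **Run probability** = fraction of ISIs below t_cut.  t_cut is the
  trough of the 3-bin-smoothed log-histogram between the main peak and
  the first bump; if no bumps are detected it falls back to peak
  location + 2× the peak's half-width.  Its complement is exactly the
  mass of the bump + tail region (closure is tested).
* **Bumps**: local maxima of the smoothed log-histogram after the main
  peak, restricted to bins holding ≥ 20 observations (Poisson noise in
  the sparse far tail would otherwise fake maxima — prominence
  threshold 0.35 in natural-log units).  The search extends to the last
  well-populated bin, not the first sparse one, because the trough
  right after the main peak is often nearly empty.  Mean spacing of
  consecutive bumps estimates the subthreshold orbital period 2π/ω
  (≈ 12 ms at I = 5).
* **Tail exponent**: maximum-likelihood exponential rate on the
  excesses above t0 (rate = 1/mean excess, SE = rate/√count, ≥ 50 tail
  points required).  t0 = last bump + one spacing; fallbacks use 12 ms
  (the linearization period) as the spacing scale.  MLE on excesses is
  bin-free and shift-invariant, unlike least squares on log-bars; the
  histogram remains available for visual cross-checks.

Both cutoffs are reported with every result so the decomposition is
auditable.

## Synthetic generators

`ISIMixtureSpec` draws from a three-component mixture — Gaussian peak,
damped Gaussian bump train at a known period, shifted exponential
tail — with closed-form component masses; the default tail starts
inside the bump region so its onset does not create a spurious local
maximum (as in real data, where the tail continues smoothly from the
bump region).  `generate_modulated_exponential` samples
exp(−λt)(1 + a·cos(2πt/P)) by rejection.  These fixtures calibrate the
extractor (rate recovery within 3 SE, spacing within one bin, ±3 SE
coverage ≥ 99% over 200 replicates).  What they do not emulate: serial
ISI correlations, slow non-stationarities, or the model-specific shape
of the initial peak — passing the calibration shows the *extractor* is
unbiased, not that any simulator is correct; the simulators are checked
separately against their own invariants and reference statistics.

## Problem sizes and tolerances

Desk-scale defaults (chosen once): 2000 pooled ISIs (ensemble of 4) for
the reference-point statistics in the test suite, 4000 (ensemble of 8)
in the acceptance script, 1000–2000 per cell in the trend grids
(areas 200/400/800 μm² at I = 6; currents 4/6/8 at area 400).
Stochastic comparisons use 3 combined standard errors (tail) or 3
binomial standard errors (run probability) at the realized ISI count.
Deterministic tolerances: fixed-point residual 1e−10, Hopf bracket
1e−3, cycle-onset resolution 0.02 — all well below the precision of the
quantities they target.

## Known limitations

* The full matrix-square-root Langevin model and the
  Ornstein-Uhlenbeck-conductance model are not implemented; the
  simulator registry (`register_simulator`) accepts them as plugins
  behind the same `SimConfig → SimResult` contract.
* Micro ISI statistics at the reference point require long runs; only
  property-level checks run at desk scale.
* Eigenvalue-based analysis assumes the studied current range
  (0–12 μA/cm²) where the fixed point is unique and the spectrum is one
  complex pair + two real eigenvalues; `linearize` raises outside that
  structure.
* The Euler-Maruyama integrator is first-order by design (it reproduces
  the published protocol); halving dt is the recommended convergence
  check for new operating points.
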