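# Methods

## Model

A two-choice decision is modeled as evidence accumulation: every `λ`
seconds one evidence sample `x ~ N(μ, σ)` is drawn and added to a tally
that starts at `x0 = 0`.  The decision "A" is made the first time the
tally reaches the upper boundary `a_A(t)`, "B" at the lower boundary
`a_B(t)`; the response time is the first-passage time (plus, for empirical
data, a non-decision latency).  As `λ → 0` the tally is a Wiener process
with drift `ξ = μ/λ` and infinitesimal variance `s² = σ²/λ`; all forward
computations work with this continuum description on the discrete grid
`t_n = nλ`.  Boundaries are unconstrained discretized functions, stored as
values `a(n)` for `n = 1..N` with the `n = 0` start values kept separately
so the backward difference `a′(n) = (a(n) − a(n−1))/λ` exists from the
first step.

Throughout, a choice/RT distribution is the pair of *defective* per-step
probabilities `P_A(n), P_B(n)` (each sums to its choice's probability).
The package convention, matching the step-wise inversion it feeds, is the
right-endpoint one: `P_X(n) = g_X(nλ)·λ` where `g_X` is the first-passage
*density*.  When such point-density arrays are compared against genuinely
binned masses (Monte Carlo counts), the helper `ks_distance` evaluates the
point-density cumulative with a trapezoid half-step correction; otherwise
the comparison would be dominated by the O(λ·max g/2) quadrature-convention
offset rather than solver error.

## Forward solver

The first-passage densities satisfy first-kind Volterra equations whose
kernel (the free transition density) diverges as `τ → t`.  Rewriting with
the kernel `Ψ(a(t), t | y, τ) = f/2·(a′(t) − (a(t) − y)/(t − τ))` gives a
second-kind system; along a smooth boundary the bracket vanishes at the
same rate `f` diverges, so the diagonal kernel limit is zero.  The solver
uses the composite trapezoidal rule on the `λ` grid; both endpoint weights
multiply vanishing factors (`g = 0` at `t0`; zero diagonal), making the
recursion explicit:

```
g_A(t_n) = −2Ψ(a_A(t_n), t_n | x0, t0)
           + 2λ Σ_{k=1}^{n−1} [ g_A(t_k) Ψ(a_A(t_n), t_n | a_A(t_k), t_k)
                              + g_B(t_k) Ψ(a_A(t_n), t_n | a_B(t_k), t_k) ]
```

and the mirrored form (signs flipped) for `g_B`.  The sign placement was
fixed empirically against the constant-boundary oracle: with boundaries ±1
and λ = 0.01 the solver agrees with the closed-form eigenfunction series to
a sup-norm of ~10⁻¹² on the per-step probabilities across
μ ∈ {0, 0.01, 0.05} and σ ∈ {0.1, 0.12}.

Degenerate input: if the two boundaries touch before the requested horizon
the solve truncates there with a warning and the surviving probability mass
is split equally between the two coincident boundaries.

**Oracles.**  (1) The classical large-time eigenfunction series for a
drifted Wiener process between two constant absorbing barriers, truncated
adaptively when the term envelope falls below 10⁻¹² (tiny alternating-sign
residues at very early times are clipped at zero).  (2) A Monte Carlo
simulator that propagates all trials one grid step at a time.  By default
the simulator applies a Brownian-bridge correction for crossings *between*
grid points: given step endpoints strictly inside the boundaries, the
bridge crossing probability against the linearly-interpolated boundary is
`exp(−2(a_prev − x_prev)(a_next − x_next)/σ²)`, which is exact for a linear
barrier (the bridge is drift-free given its endpoints).  Without it the raw
discrete walk observes the process only at grid times and its first
passages are biased late by an effective barrier shift of ≈ 0.583·s·√λ —
several percent of the CDF at the default λ — which would make the
simulator useless as a continuous-time oracle.  `bridge=False` recovers the
raw walk.

## Inverse method

The point-wise phase steps through the grid.  At step `n` it evaluates, for
candidate levels `c_X(i) = start_X · i/I` (`I = grid_cells`, increment
`l = start/I`, default `l = 0.01`), the density each candidate would
produce given everything already committed, and commits the argmin of
`|q_X(i)·λ − P_X(n)|` per boundary (ties break to the smaller index, i.e.
the level nearest zero; the whole inversion is deterministic).  Because the
solver only ever looks backward, each step's candidate scores reuse all
previously committed densities; the full inversion is O(N²·I).
Targets are renormalized to total mass 1 first; the truncated mass is
recorded on the result.

Two guard rules stabilize the search:

* **Mass floor** (`target_mass_floor = 1e−12`): a step whose target mass is
  below numerical noise carries no information about the boundary, and the
  argmin would otherwise latch onto floating-point noise through the
  backward-difference derivative term (the derivative enters the kernel
  with weight 1/λ, so a one-cell change swings the candidate density
  enormously at near-zero mass).  Such steps keep the previous boundary
  value.  The same rule covers the all-zero tail beyond the last
  positive-mass step, where boundaries are reported as held.
* **Critical-step detection**: the corrective phase takes over at the first
  pair of consecutive steps whose residual exceeds
  `max(residual_tol·(P_A + P_B), 1e−5)`, once the cumulative target mass
  exceeds 1% (earlier, per-step masses are so small that relative residuals
  measure discretization noise, not failure).  `residual_tol` defaults to
  2%.  A looser band (e.g. 10%) provably never fires on the dominant
  failure mode: each step's density pins the boundary *slope* a factor
  ~1/λ more strongly than its level, so level errors drift unboundedly
  while per-step residuals stay small (on the exponential-collapse round
  trip the drift exceeds 9 grid cells inside the 95% region before a 10%
  band reacts).

**Piecewise-linear corrective phase.**  Steps beyond the critical step are
fitted in connected segments of `refine_segment_len` (default 3) steps:
the segment's endpoint level per boundary is chosen by direct search over
the candidate grid (two coordinate-descent sweeps of a coarse-then-local
two-stage search; interior steps linearly interpolated), with within-segment
coupling of the two densities handled exactly.  The segment objective is
the summed per-step deviation *plus* the deviation of the cumulative
absorbed mass per boundary at the segment end.  The budget term matters:
a purely per-step objective is myopic in low-mass regions — producing no
absorption at all looks locally optimal, stranding unabsorbed survivors
that the target says should already have been absorbed.  The point-wise
values are kept whenever they score no worse, so refinement never increases
the total objective.

**Symmetric variant.**  A single level per step with `a_B(n) = −a_A(n)`,
scored by the combined deviation on both boundaries; start values must be
mirrored.  Greedy left-to-right construction is structurally myopic under
drifted evidence (it can satisfy the high-mass boundary early, then retreat
upward and strand the minority side's mass), so `equate_models` evaluates a
second global basin — the elementwise symmetrization of the unconstrained
solution, forward-solved as one trajectory — and returns whichever
regenerates the target more closely.  The corrective phase also accepts
such a trajectory as an extra per-segment candidate (`guide_upper`).

**Distance.**  `boundary_residual` is the total-variation distance between
defective joint distributions:
`½(Σ_n |ΔP_A,n| + |ΔP_B,n| + |Δ residual mass|)`.

## Accumulator model

The race model keeps two non-negative tallies; each sample moves exactly
one of them (`x > 0` adds `x` to A's, `x < 0` adds `|x|` to B's), and the
first to reach the criterion `K` wins.  The deterministic mapping
`(μ, σ) → (P_A, P_B)` is computed by propagating the joint sub-threshold
mass on a `C × C` lattice (`C = state_cells`, default 400; cell width
`K/C`).  Increments are discretized by CDF differences over half-cell-
aligned bins (mass-preserving), with everything beyond `C` cells lumped
into one absorbing entry, so probability is conserved exactly; each step is
two FFT convolutions, one per axis.  A grid is rejected as too coarse when
more than 5% of positive samples cannot move the tally one cell.  The
recursion agrees with a 10⁶-trial direct simulation to ~2·10⁻⁴ on the
choice probability and TV ≈ 0.003 on the full distribution; doubling
`state_cells` moves the choice probability by < 10⁻⁴.

Only `K/σ` matters up to time rescaling, so the default `K = 1` (matching
the unit diffusion start boundaries) is a normalization, exposed as a
parameter.

**Equating configuration.**  The equivalence runs use start values ±1.2
with 120 grid cells (the same `l = 0.01` increment).  With σ shared
between the two models the boundary scale is *not* a free normalization,
and capping candidates at ±1 binds: the accumulator's thin RT head demands
an effectively higher early boundary, and the forced head overshoot
(~0.006) starves the tail, flooring the achievable TV near 0.024 in the
strong-drift cases.  With the ±1.2 start all four standard evidence
distributions — μ ∈ {0.01, 0.05} × σ ∈ {0.1, 0.12} — reach TV ≤ 0.018
(unconstrained) at horizon 300.

**Discrete analog.**  For ±1 increments, a race to `K` is *exactly* a
random walk with boundaries `±(2K − n)` (one unit of collapse per step):
A's tally hits `K` at step `n` iff the walk sits at `2K − n`.
`enumerate_race` / `enumerate_walk` verify this by exhaustive prefix-tree
enumeration.

## Empirical pipeline

For non-evidential stimuli the drift is fixed at zero and every subject is
assumed to share the per-sample evidence SD `σ = 0.01` (read as the second
argument of `N(0, 0.01)` being an SD; exposed as a flag since the
variance-vs-SD convention is ambiguous).  The starting boundary values then
become free parameters.  Pipeline:

1. **Shift**: subtract the condition's minimum RT minus a 1 ms guard
   (zero first-passage times are impossible under the model).  This is a
   rough non-decision-time estimate; it *over*-shifts by the minimum
   first-passage time (~40 ms at the default geometry), a known bias.
2. **Weibull smoothing**: maximum-likelihood shape/scale per alternative
   (location fixed at zero), because the inversion is unstable against the
   multimodality of raw binned histograms.  Direct inversion of raw
   histograms is deliberately not offered in the pipeline.
3. **Targets**: `P_X(n) = p_X·(F_X(nλ) − F_X((n−1)λ))` from the fitted CDF
   (deterministic; no resampling).
4. **Decile chi-square**: 10 bins at the fitted deciles, expected `n/10`
   each; the statistic is referred to χ² with `10 − 1 − n_estimated`
   degrees of freedom.  The reporting convention is `n_estimated = 2`
   (d.f. = 7).  Note this reference is conventional, not exact: parameters
   estimated from raw (unbinned) data place the statistic stochastically
   between χ²₇ and χ²₉, and its p-values are measurably non-uniform under
   the true model (KS ≈ 0.07 from uniform at 1000 replicates).  With known
   parameters (`n_estimated = 0`, d.f. = 9) the statistic is an exact
   multinomial chi-square and the p-values are uniform — that is the
   calibration check the tests run.
5. **Free-start inversion**: a coarse geometric scan of 20 symmetric start
   values bracketing the moment guess `s·√(mean RT)`, a 7-point ~5%-step
   fine scan, then a 3×3 ±5% asymmetric local search, each scored by the
   point-wise inversion's achieved-vs-target TV; the winner gets the full
   corrective phase.

**What the synthetic generators emulate — and what they don't.**  The
Weibull fixture generator mimics a psychophysical subject run: thousands of
trials, ~0.3 s non-decision shift, unimodal right-skewed RTs under 2 s,
near-even choices.  The diffusion fixture draws trial-level first passages
from a known zero-drift collapsing-boundary model plus a fixed shift.
Neither includes trial-to-trial parameter variability, lapses,
sequential effects, or condition mixtures, so passing recovery tests shows
the pipeline inverts *its own model class* faithfully — not that real data
satisfy these assumptions.

**Recovery behavior** (10⁴ trials, truth `a(t) = 0.08·e^(−t/1.2)`, shift
0.3 s): achieved-vs-target TV ≈ 0.009; boundary-shape correlation ≈ 0.95
over the central mass region (2.5%–95% of target mass).  The head (first
~4 steps) is excluded from that region because the Weibull's power-law
density head cannot represent the essential singularity of a first-passage
density near zero, which forces a compensating local dip in the recovered
boundary; the tail beyond 95% is excluded because the data no longer
constrain it.  The recovered start values run ~13% low — the joint,
seed-stable effect of the min-RT over-shift and the Weibull head mismatch —
so start values should be read as effective, not anatomical, parameters.

## Numerical and design choices, briefly

* Quadrature: composite trapezoid on the λ grid; diagonal kernel = its
  analytic limit (zero) for smooth boundaries; second-order accurate, and
  halving λ monotonically shrinks the discrepancy to a fine-grid reference.
* Horizons are chosen so the residual (unabsorbed) mass is below 10⁻³:
  N = 900 for constant unit boundaries at λ = 0.01, 450 for the
  exponential-collapse cases, 300 for the accumulator equivalences, 250 for
  the empirical fits.  These keep every analysis comfortably fast on one
  core.
* All inversion paths are deterministic; the only randomness is in the
  Monte Carlo simulators and data generators, each taking one integer seed
  (`numpy.random.default_rng`).
* Boundary monotonicity is *not* enforced; recovered boundaries may be
  locally non-monotone (and are, at the one-cell level).
* CSV artifacts carry 12 significant digits; step indices are 1-based with
  the `n = 0` start row included in boundary files.

## Known limitations

* No Ornstein–Uhlenbeck or leaky accrual; no trial-to-trial variability in
  drift or starting point; no urgency-gating signals.
* The inverse problem's two-boundary well-posedness is an open theoretical
  question; the method returns *a* boundary pair that regenerates the
  target to the reported distance, with no uniqueness or uncertainty
  quantification (no credible intervals).
* The min-RT shift is a crude non-decision-time estimate and biases start
  values low (see above).
* Equivalence quality is quantified in the package's right-endpoint pmf
  convention at λ = 0.01; distances are not invariant to that convention.
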