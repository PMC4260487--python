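# tvbounds

Forward and inverse first-passage-time machinery for two-choice diffusion
models of decision making with **time-varying decision boundaries**.

Sequential-sampling models assume a decision maker accumulates noisy
evidence — one Gaussian sample `x ~ N(μ, σ)` every `λ` seconds — until a
tally first reaches an upper boundary `a_A(t)` (choice A) or a lower
boundary `a_B(t)` (choice B).  In the continuum limit the tally is a Wiener
process with drift `ξ = μ/λ` and infinitesimal variance `s² = σ²/λ`.  Most
applications fix the boundaries to constants; this package treats them as
free *functions of time*, and works in both directions:

* **Forward**: given `(μ, σ, a_A, a_B)`, compute the choice probability and
  the (defective) response-time distributions `(p, r_A, r_B)`.  The
  first-passage densities `g_A, g_B` satisfy coupled Volterra integral
  equations linking them to the free Gaussian transition density
  `f(x, t | y, τ)`; the raw kernel is singular as `τ → t`, so the solver
  steps the second-kind system obtained with the singularity-removed kernel

  `Ψ(a(t), t | y, τ) = f(a(t), t | y, τ)/2 · (a′(t) − (a(t) − y)/(t − τ))`,

  which vanishes on the diagonal for smooth boundaries.
* **Inverse**: given target per-step probabilities `P_A(n), P_B(n)` and a
  known evidence distribution, recover the boundaries that generate them —
  a step-wise grid search (each step's boundary level is chosen so the
  regenerated density matches the target mass, `g_X(nλ)·λ = P_X(n)`),
  followed by a piecewise-linear corrective fit of the late boundary where
  recursion error accumulates.  A symmetry-constrained variant
  (`a_B = −a_A`) is included.

Two applications are built in:

1. **Model equivalence** — a Gaussian **accumulator (race) model** (two
   separate tallies, each collecting only the evidence favoring its
   alternative, racing to a criterion `K`) maps `(μ, σ) → (p, r_A, r_B)`
   with *no* boundary freedom.  `equate_models` finds the time-varying
   diffusion boundaries that reproduce it, generalizing the classical exact
   discrete result (a ±1 random walk with boundaries decreasing one unit
   per step equals a race model — verified here by exhaustive enumeration).
2. **Empirical RT fitting** — for non-evidential stimuli (zero drift),
   recover individual-level boundaries from raw `(rt, choice)` records:
   shift by the minimum RT (non-decision time), smooth each alternative's
   RTs with a maximum-likelihood shifted Weibull, assess fit with a decile
   Pearson chi-square (d.f. = 7), discretize the fitted CDF into per-step
   targets, and invert with free boundary starting values.

## Worked example

Equate a diffusion process to an accumulator with strong drift
(μ = 0.05, σ = 0.10 per 10 ms sample, criterion K = 1):

```python
from tvbounds import AccumulatorSpec, InversionConfig, equate_models

cfg = InversionConfig(horizon=300, grid_cells=120, start_upper=1.2, start_lower=-1.2)
result, target = equate_models(AccumulatorSpec(mu=0.05, sigma=0.10), cfg)

print(f"accumulator p(A)         = {target.p_upper:.4f}")
print(f"diffusion   p(A)         = {result.achieved.p_upper:.4f}")
print(f"total-variation distance = {result.distance:.4f}")
print(f"mean RT (choice A)       = {target.mean_rt('upper'):.3f} s target, "
      f"{result.achieved.mean_rt('upper'):.3f} s achieved")
```

prints

```
accumulator p(A)         = 0.9935
diffusion   p(A)         = 0.9937
total-variation distance = 0.0157
mean RT (choice A)       = 0.153 s target, 0.152 s achieved
```

The accumulator chooses A on 99.35% of trials with a mean RT of 153 ms; the
diffusion model with the recovered collapsing boundaries reproduces the full
joint choice/RT distribution to within a total-variation distance of 0.016.
In this regime the recovered boundaries are asymmetric: the lower boundary
converges toward zero sooner than the upper one.  `result.bounds` holds the
boundary arrays, `result.main_until` the last step solved by the point-wise
phase (the rest comes from the piecewise-linear corrective fit).

The same machinery is available from the shell:

```bash
tvbounds equate --mu 0.05 --sigma 0.10 --out-prefix results/eq   # boundaries + panels
tvbounds make-fixture --n-trials 8000 --seed 1 --out data.csv    # synthetic RT data
tvbounds fit-empirical --data data.csv --sigma 0.01 --out-prefix results/fit
tvbounds forward / invert / simulate                             # lower-level pieces
```

## Layout

| module | contents |
| --- | --- |
| `tvbounds.types` | `EvidenceDistribution`, `BoundaryPair`, `ChoiceRTDistribution` |
| `tvbounds.diffusion` | transition density, Ψ kernel, Volterra solver, series + Monte Carlo oracles |
| `tvbounds.inversion` | grid-search inversion, piecewise-linear refinement, symmetric variant |
| `tvbounds.accumulator` | race-model recursion and simulation, model equating, discrete enumeration |
| `tvbounds.empirical` | RT shift, Weibull fitting, chi-square GOF, free-start boundary fitting, data synthesis |
| `tvbounds.io` / `.plotting` / `.cli` | validated CSV/JSON readers and writers, panel figures, `tvbounds` CLI |

See `docs/methods.md` for the model assumptions, numerical choices, and
known limitations.
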