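"""Gaussian accumulator (race) model and its equivalence with diffusion.

An accumulator model keeps two separate non-negative evidence tallies, one
per alternative.  Each sampling step draws a single value ``x ~ N(mu, sigma)``;
a positive sample adds ``x`` to tally A, a negative one adds ``|x|`` to
tally B.  The first tally to reach the (symmetric) criterion ``K`` wins, so
the model maps ``(mu, sigma) -> (p, r_A, r_B)`` directly — no boundary
parameters.  This module computes that mapping two ways (an exact lattice
Markov-chain recursion and plain Monte Carlo), and composes the inversion
machinery to find the time-varying diffusion boundaries that reproduce it
(:func:`equate_models`).

The discrete analog of that equivalence is exact: for ``+-1`` unit
increments, a random walk with boundaries that start at ``2K - 1`` and
decrease one unit per step reproduces a K-sample race model's choice and
RT distributions (:func:`enumerate_race`, :func:`enumerate_walk`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import norm

from .diffusion import solve_fpt
from .inversion import (
    InversionConfig,
    InversionResult,
    boundary_residual,
    invert_boundaries,
    invert_symmetric,
    piecewise_refine,
)
from .types import ChoiceRTDistribution, EvidenceDistribution

__all__ = [
    "AccumulatorSpec",
    "ResolutionError",
    "accumulator_fpt",
    "accumulator_simulate",
    "equate_models",
    "enumerate_race",
    "enumerate_walk",
]


class ResolutionError(ValueError):
    """Raised when the tally grid is too coarse for the evidence scale."""


@dataclass(frozen=True)
class AccumulatorSpec:
    """Accumulator model parameters.

    ``mu``/``sigma`` describe the per-sample Gaussian evidence, ``threshold``
    the common criterion ``K`` both tallies race toward, ``step`` the sample
    duration in seconds, and ``state_cells`` the resolution of the tally
    lattice used by the deterministic recursion.  Only the ratio
    ``threshold / sigma`` matters up to a time rescaling, so the default
    ``K = 1`` (matching unit diffusion start boundaries) loses no generality.
    """

    mu: float
    sigma: float
    threshold: float = 1.0
    step: float = 0.01
    state_cells: int = 400

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError("threshold must be > 0")
        if self.state_cells < 50:
            raise ValueError("state_cells must be >= 50")
        if not (self.sigma > 0 and self.step > 0):
            raise ValueError("sigma and step must be positive")

    @property
    def evidence(self) -> EvidenceDistribution:
        return EvidenceDistribution(self.mu, self.sigma, self.step)


def _increment_kernels(spec: AccumulatorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cell-binned distributions of the positive and |negative| increments.

    Entry ``d`` of each kernel is the probability that one sample moves the
    corresponding tally by ``d`` cells: mass of ``x`` in
    ``((d - 1/2) w, (d + 1/2) w)`` restricted to the relevant sign, with all
    mass beyond ``C`` cells lumped into the last entry (it absorbs from any
    sub-threshold cell).  CDF differences preserve total mass exactly.
    """
    C = spec.state_cells
    w = spec.threshold / C
    half_edges = (np.arange(C) + 0.5) * w  # 0.5w, 1.5w, ..., (C-0.5)w
    cdf0 = norm.cdf(0.0, loc=spec.mu, scale=spec.sigma)
    cdf_up = norm.cdf(half_edges, loc=spec.mu, scale=spec.sigma)
    pos = np.empty(C + 1)
    pos[0] = cdf_up[0] - cdf0
    pos[1:C] = np.diff(cdf_up)
    pos[C] = 1.0 - cdf_up[-1]  # lump: absorbs from any sub-threshold cell
    cdf_dn = norm.cdf(-half_edges, loc=spec.mu, scale=spec.sigma)
    neg = np.empty(C + 1)
    neg[0] = cdf0 - cdf_dn[0]
    neg[1:C] = -np.diff(cdf_dn)
    neg[C] = cdf_dn[-1]
    return pos, neg


def accumulator_fpt(spec: AccumulatorSpec, horizon: int) -> ChoiceRTDistribution:
    """Defective choice/RT distribution by deterministic lattice recursion.

    The joint sub-threshold mass over the two tallies is propagated on a
    ``C x C`` lattice (cell width ``K / C``); each step convolves one axis
    with the positive-increment kernel and the other with the
    negative-increment kernel, and mass pushed to or past ``K`` on either
    axis at step ``n`` is banked into ``P_A(n)`` / ``P_B(n)``.
    """
    pos, neg = _increment_kernels(spec)
    C = spec.state_cells
    # a grid is too coarse when an appreciable share of positive samples
    # cannot move the tally even one cell
    stay = pos[0] / max(pos.sum(), 1e-300)
    if stay > 0.05:
        raise ResolutionError(
            f"state_cells={C} too coarse: {stay:.1%} of positive samples move < 1 cell; "
            "increase state_cells"
        )
    M = np.zeros((C, C))
    M[0, 0] = 1.0
    p_a = np.empty(horizon)
    p_b = np.empty(horizon)
    for n in range(horizon):
        full_a = fftconvolve(M, pos[:, None], axes=0)
        p_a[n] = full_a[C:, :].sum()
        full_b = fftconvolve(M, neg[None, :], axes=1)
        p_b[n] = full_b[:, C:].sum()
        M = full_a[:C, :] + full_b[:, :C]
        np.clip(M, 0.0, None, out=M)  # FFT roundoff can leave ~1e-17 negatives
    dist = ChoiceRTDistribution(p_a, p_b, spec.step)
    if dist.total_mass < 0.999:
        warnings.warn(
            f"horizon {horizon} leaves {1 - dist.total_mass:.2%} of mass unabsorbed",
            RuntimeWarning,
            stacklevel=2,
        )
    return dist


def accumulator_simulate(spec: AccumulatorSpec, n_trials: int, horizon: int, seed: int) -> ChoiceRTDistribution:
    """Trial-level Monte Carlo of the race; reproducible given ``seed``.

    A single Gaussian sample per step moves exactly one tally, so the two
    tallies can never cross their criterion on the same sample; the uniform
    tie-break is therefore vestigial but kept for safety with degenerate
    floating-point input.  Trials alive after ``horizon`` steps land in the
    overflow bucket.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    sa = np.zeros(n_trials)
    sb = np.zeros(n_trials)
    idx = np.arange(n_trials)
    steps = np.zeros(n_trials, dtype=np.int64)
    choices = np.zeros(n_trials, dtype=np.int8)
    K = spec.threshold
    for n in range(1, horizon + 1):
        if idx.size == 0:
            break
        x = rng.normal(spec.mu, spec.sigma, size=idx.size)
        sa = sa + np.where(x > 0, x, 0.0)
        sb = sb + np.where(x < 0, -x, 0.0)
        hit_a = sa >= K
        hit_b = sb >= K
        both = hit_a & hit_b
        if both.any():  # unreachable with continuous increments; split at random
            flip = rng.random(int(both.sum())) < 0.5
            hit_b[np.nonzero(both)[0][flip]] = False
            hit_a[np.nonzero(both)[0][~flip]] = False
        done = hit_a | hit_b
        if done.any():
            steps[idx[hit_a]] = n
            choices[idx[hit_a]] = 1
            steps[idx[hit_b]] = n
            choices[idx[hit_b]] = -1
            keep = ~done
            idx, sa, sb = idx[keep], sa[keep], sb[keep]
    pmf_a = np.bincount(steps[choices == 1], minlength=horizon + 1)[1:] / n_trials
    pmf_b = np.bincount(steps[choices == -1], minlength=horizon + 1)[1:] / n_trials
    overflow = float((choices == 0).sum()) / n_trials
    return ChoiceRTDistribution(pmf_a, pmf_b, spec.step, overflow=overflow)


def equate_models(
    spec: AccumulatorSpec,
    cfg: InversionConfig,
    symmetric: bool = False,
    refine: bool = True,
) -> tuple[InversionResult, ChoiceRTDistribution]:
    """Find diffusion boundaries that reproduce an accumulator model.

    Generates the accumulator's choice/RT distribution with the same Gaussian
    evidence, inverts it (optionally under the symmetry constraint), applies
    the piecewise-linear corrective phase, and reports the achieved-vs-target
    total-variation distance on the result.  Returns ``(result, target)``.

    The symmetric search has two global basins: the greedy left-to-right
    construction, and the elementwise symmetrization of the unconstrained
    solution solved forward as a whole trajectory.  The greedy construction
    is myopic under drifted evidence (it can satisfy the high-mass boundary
    early and then retreat, stranding the other side's mass), so the variant
    evaluates both and returns whichever regenerates the target more
    closely.
    """
    target = accumulator_fpt(spec, cfg.horizon)
    ev = spec.evidence
    tgt_norm = target.renormalized()
    invert = invert_symmetric if symmetric else invert_boundaries
    result = invert(target, ev, cfg)
    guide = None
    if symmetric:
        free = invert_boundaries(target, ev, cfg)
        if refine and free.main_until < cfg.horizon:
            free = piecewise_refine(free, target, ev, cfg)
        guide = 0.5 * (free.bounds.upper + np.abs(free.bounds.lower))
    if refine and result.main_until < cfg.horizon:
        result = piecewise_refine(result, target, ev, cfg, guide_upper=guide)
    result.distance = boundary_residual(result.achieved, tgt_norm)
    if symmetric and guide is not None:
        from .types import BoundaryPair

        sym_bounds = BoundaryPair(guide, -guide, cfg.start_upper, cfg.start_lower, cfg.step)
        sym_achieved = solve_fpt(sym_bounds, ev)
        sym_tv = boundary_residual(sym_achieved, tgt_norm)
        if sym_tv < result.distance:
            result = InversionResult(
                bounds=sym_bounds,
                main_until=result.main_until,
                residuals=np.abs(sym_achieved.pmf_upper - tgt_norm.pmf_upper)
                + np.abs(sym_achieved.pmf_lower - tgt_norm.pmf_lower),
                achieved=sym_achieved,
                symmetric=True,
                refined=True,
                converged=True,
                target_mass=target.total_mass,
                last_target_step=result.last_target_step,
                distance=sym_tv,
            )
    return result, target


# ---------------------------------------------------------------------------
# discrete analog: race model vs unit random walk (exhaustive enumeration)
# ---------------------------------------------------------------------------

def enumerate_race(threshold: int, n_max: int, p: float) -> dict[tuple[int, int], float]:
    """Exact outcome distribution of a +-1 race model by enumerating sign sequences.

    Each step is +1 with probability ``p`` (counted by tally A) or -1
    (counted by tally B); the first tally to reach ``threshold`` wins.
    Returns ``{(choice, step): probability}`` with choice +1/-1, for
    sequences up to length ``n_max``.
    """
    out: dict[tuple[int, int], float] = {}

    def walk(n: int, a: int, b: int, prob: float) -> None:
        if a >= threshold or b >= threshold:
            key = (1 if a >= threshold else -1, n)
            out[key] = out.get(key, 0.0) + prob
            return
        if n == n_max:
            return
        walk(n + 1, a + 1, b, prob * p)
        walk(n + 1, a, b + 1, prob * (1.0 - p))

    walk(0, 0, 0, 1.0)
    return out


def enumerate_walk(
    upper: np.ndarray, lower: np.ndarray, n_max: int, p: float
) -> dict[tuple[int, int], float]:
    """Exact outcome distribution of a +-1 random walk with step-indexed boundaries."""
    out: dict[tuple[int, int], float] = {}

    def walk(n: int, x: int, prob: float) -> None:
        if n > 0 and (x >= upper[n - 1] or x <= lower[n - 1]):
            key = (1 if x >= upper[n - 1] else -1, n)
            out[key] = out.get(key, 0.0) + prob
            return
        if n == n_max:
            return
        walk(n + 1, x + 1, prob * p)
        walk(n + 1, x - 1, prob * (1.0 - p))

    walk(0, 0, 1.0)
    return out
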