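"""Inverse first-passage-time problem: boundaries from choice/RT targets.

Given per-step target probabilities ``P_A(n)``, ``P_B(n)`` and a known
Gaussian evidence distribution, the point-wise algorithm steps through the
grid times and, at each step, grid-searches the boundary level whose
first-passage density (given everything already fixed) best matches the
target mass, exploiting the fact that the stepwise Volterra recursion only
ever looks backward.  Because numerical precision errors accumulate along
the recursion, a corrective second phase refits the late portion of each
boundary as a connected piecewise-linear curve by direct search
(:func:`piecewise_refine`).

A symmetry-constrained variant (:func:`invert_symmetric`) searches a single
level per step with ``a_B(n) = -a_A(n)``, scoring candidates by the combined
deviation on both boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diffusion import VolterraSolver
from .types import BoundaryPair, ChoiceRTDistribution, DiffusionState, EvidenceDistribution

__all__ = [
    "InversionConfig",
    "InversionResult",
    "invert_boundaries",
    "invert_symmetric",
    "piecewise_refine",
    "boundary_residual",
]


@dataclass(frozen=True)
class InversionConfig:
    """Tunable parameters of the grid-search inversion.

    Attributes
    ----------
    grid_cells : int
        Number of candidate boundary levels ``I``; the candidate grid is
        ``c(i) = start * i/I`` for ``i = 1..I`` (increment ``l = start/I``,
        i.e. ``l = 0.01`` at the defaults).
    step : float
        Sampling-step duration ``lambda`` in seconds.
    horizon : int
        Number of steps ``N`` to solve for.
    refine_segment_len : int
        Steps per piecewise-linear segment in the corrective phase (2 or 3).
    residual_tol : float
        Relative per-step residual (fraction of the target per-step mass)
        that, when exceeded on two consecutive steps, marks the critical
        step where the corrective phase takes over.
    residual_floor : float
        Absolute floor under the relative tolerance, so vanishing target
        mass in the deep tail does not trigger the switch spuriously.
    start_upper, start_lower : float
        Boundary values at ``t = 0``; ``+1/-1`` by default (the boundaries
        scale with sigma without changing shape, so unit starts lose no
        generality unless the starts themselves are free parameters).
    """

    grid_cells: int = 100
    step: float = 0.01
    horizon: int = 400
    refine_segment_len: int = 3
    residual_tol: float = 0.02
    residual_floor: float = 1e-5
    target_mass_floor: float = 1e-12
    detect_after_mass: float = 0.01
    start_upper: float = 1.0
    start_lower: float = -1.0

    def __post_init__(self) -> None:
        if self.grid_cells < 10:
            raise ValueError("grid_cells must be >= 10")
        if self.refine_segment_len not in (2, 3):
            raise ValueError("refine_segment_len must be 2 or 3")
        if not (self.residual_tol > 0):
            raise ValueError("residual_tol must be > 0")
        if not (self.step > 0 and self.horizon > 0):
            raise ValueError("step and horizon must be positive")
        if not (self.start_upper > 0 > self.start_lower):
            raise ValueError("need start_upper > 0 > start_lower")

    def candidate_grid(self, side: str) -> np.ndarray:
        i = np.arange(1, self.grid_cells + 1, dtype=float) / self.grid_cells
        return self.start_upper * i if side == "upper" else self.start_lower * i

    @property
    def cell_size(self) -> float:
        """Grid increment ``l`` on the upper side."""
        return self.start_upper / self.grid_cells


@dataclass
class InversionResult:
    """Outcome of an inversion run.

    ``main_until`` is the last step solved by the point-wise phase (the
    critical step); ``residuals`` holds the per-step absolute deviation
    ``|q_A*step - P_A| + |q_B*step - P_B|``; ``achieved`` is the choice/RT
    distribution regenerated from the recovered boundaries.  ``symmetric``
    records which variant produced the result, ``refined`` whether the
    corrective phase ran, ``converged`` whether it reduced the tail
    objective, and ``target_mass`` the captured mass of the target before
    renormalization (1 minus the recorded truncation).  ``last_target_step``
    is the last step with positive target mass; boundary values beyond it
    are unconstrained by the data.
    """

    bounds: BoundaryPair
    main_until: int
    residuals: np.ndarray
    achieved: ChoiceRTDistribution
    symmetric: bool = False
    refined: bool = False
    converged: bool = True
    target_mass: float = 1.0
    last_target_step: int = 0
    distance: float | None = None


def boundary_residual(achieved: ChoiceRTDistribution, target: ChoiceRTDistribution) -> float:
    """Total-variation distance between two defective choice/RT distributions.

    ``0.5 * (sum_n |dP_A,n| + |dP_B,n| + |d residual|)`` where the residual is
    the mass each distribution leaves beyond the grid (including overflow
    buckets).  Zero for identical inputs; one for proper distributions with
    disjoint support.
    """
    if achieved.n_steps != target.n_steps or not math.isclose(achieved.step, target.step, rel_tol=1e-12):
        raise ValueError("distributions must share the same step and horizon")
    d = np.abs(achieved.pmf_upper - target.pmf_upper).sum()
    d += np.abs(achieved.pmf_lower - target.pmf_lower).sum()
    r_a = max(0.0, 1.0 - achieved.total_mass)
    r_t = max(0.0, 1.0 - target.total_mass)
    return 0.5 * (d + abs(r_a - r_t))


def _prepare_target(target: ChoiceRTDistribution, ev: EvidenceDistribution, cfg: InversionConfig):
    if not math.isclose(target.step, cfg.step, rel_tol=1e-12) or not math.isclose(ev.step, cfg.step, rel_tol=1e-12):
        raise ValueError("target, evidence distribution and config must share the same step")
    mass = target.total_mass
    tgt = target.renormalized()
    pos = np.nonzero(tgt.pmf_upper + tgt.pmf_lower > 0)[0]
    last_pos = int(pos[-1]) + 1 if pos.size else 0
    horizon = min(cfg.horizon, tgt.n_steps)
    return tgt, mass, last_pos, horizon


def _invert(target: ChoiceRTDistribution, ev: EvidenceDistribution, cfg: InversionConfig, symmetric: bool) -> InversionResult:
    tgt, mass, last_pos, horizon = _prepare_target(target, ev, cfg)
    if symmetric and not math.isclose(cfg.start_upper, -cfg.start_lower, rel_tol=1e-12):
        raise ValueError("symmetric inversion requires start_lower = -start_upper")
    cand_up = cfg.candidate_grid("upper")
    cand_lo = cfg.candidate_grid("lower")
    lam = cfg.step
    solver = VolterraSolver(ev, cfg.start_upper, cfg.start_lower, DiffusionState())
    residuals = np.empty(horizon)
    critical: int | None = None
    consecutive = 0
    floor = cfg.target_mass_floor
    cum_mass = 0.0
    for n in range(1, horizon + 1):
        p_a = tgt.pmf_upper[n - 1]
        p_b = tgt.pmf_lower[n - 1]
        cum_mass += p_a + p_b
        prev1, prev2 = solver._prev()
        # Steps with (numerically) no target mass carry no information about
        # the boundary level: hold the previous value instead of letting the
        # argmin latch onto floating-point noise.
        hold_a = p_a < floor
        hold_b = p_b < floor
        if hold_a and hold_b:
            g1, g2 = solver.commit(prev1, prev2)
            residuals[n - 1] = abs(g1 * lam - p_a) + abs(g2 * lam - p_b)
            consecutive = 0
            continue
        q1, q2 = solver.candidate_densities(cand_up, cand_lo)
        r_a = np.abs(q1 * lam - p_a)
        r_b = np.abs(q2 * lam - p_b)
        if symmetric:
            if hold_a or hold_b:
                i = int(np.argmin(np.abs(cand_up - prev1)))
            else:
                i = int(np.argmin(r_a + r_b))  # ties -> smaller index (level nearer zero)
            i_a = i_b = i
        else:
            i_a = int(np.argmin(np.abs(cand_up - prev1))) if hold_a else int(np.argmin(r_a))
            i_b = int(np.argmin(np.abs(cand_lo - prev2))) if hold_b else int(np.argmin(r_b))
        residuals[n - 1] = r_a[i_a] + r_b[i_b]
        solver.commit(cand_up[i_a], cand_lo[i_b], float(q1[i_a]), float(q2[i_b]))
        # critical-step detection: two consecutive steps failing the tolerance.
        # Suppressed in the distribution head (cumulative mass below
        # detect_after_mass), where per-step masses are so small that relative
        # residuals reflect discretization noise, not point-wise failure.
        if cum_mass < cfg.detect_after_mass:
            consecutive = 0
            continue
        tol_n = max(cfg.residual_tol * (p_a + p_b), cfg.residual_floor)
        if residuals[n - 1] > tol_n:
            consecutive += 1
            if consecutive >= 2 and critical is None:
                critical = n - 2  # last step before the first of the two failures
        else:
            consecutive = 0
    bounds = BoundaryPair(solver.upper_values, solver.lower_values, cfg.start_upper, cfg.start_lower, lam)
    achieved = ChoiceRTDistribution(
        np.clip(solver.g_upper * lam, 0.0, None), np.clip(solver.g_lower * lam, 0.0, None), lam
    )
    main_until = horizon if critical is None else max(critical, 0)
    tgt_grid = ChoiceRTDistribution(tgt.pmf_upper[:horizon], tgt.pmf_lower[:horizon], lam)
    return InversionResult(
        bounds=bounds,
        main_until=main_until,
        residuals=residuals,
        achieved=achieved,
        symmetric=symmetric,
        target_mass=mass,
        last_target_step=last_pos,
        distance=boundary_residual(achieved, tgt_grid),
    )


def invert_boundaries(target: ChoiceRTDistribution, ev: EvidenceDistribution, cfg: InversionConfig) -> InversionResult:
    """Point-wise grid-search recovery of the two boundaries.

    The target is renormalized to total mass 1 (the truncated mass is
    recorded on the result).  At each step the candidate levels
    ``c_A(i) = start_upper * i/I`` and ``c_B(i) = start_lower * i/I`` are
    scored by the forward solver's first-passage density given all previously
    fixed values, and the argmin of ``|q_X(i)*step - P_X(n)|`` is committed
    (ties break to the smaller index, i.e. the level closest to zero).
    """
    return _invert(target, ev, cfg, symmetric=False)


def invert_symmetric(target: ChoiceRTDistribution, ev: EvidenceDistribution, cfg: InversionConfig) -> InversionResult:
    """Inversion constrained to mirror-symmetric boundaries ``a_B = -a_A``."""
    return _invert(target, ev, cfg, symmetric=True)


# ---------------------------------------------------------------------------
# corrective piecewise-linear phase
# ---------------------------------------------------------------------------

def _linear_segments(prev: float, endpoints: np.ndarray, L: int) -> np.ndarray:
    """Linear interpolation from ``prev`` to each endpoint over ``L`` steps, shape (S, L)."""
    frac = np.arange(1, L + 1) / L
    return prev + (endpoints[:, None] - prev) * frac[None, :]


def _segment_objective(
    q1: np.ndarray, q2: np.ndarray, p_a: np.ndarray, p_b: np.ndarray, lam: float, budget
) -> np.ndarray:
    """Per-step deviation plus a cumulative mass-budget deviation at segment end.

    The per-step term alone is myopic: in low-mass regions it prefers
    producing no absorption at all, letting unabsorbed survivors pile up
    without ever paying for them.  The budget term compares the cumulative
    absorbed mass per boundary at the segment end with the target's, giving
    the greedy per-segment search the global mass signal.
    """
    obj = np.abs(q1 * lam - p_a[None, :]).sum(axis=1) + np.abs(q2 * lam - p_b[None, :]).sum(axis=1)
    cum_a_prev, cum_b_prev, ctgt_a, ctgt_b = budget
    obj = obj + np.abs(cum_a_prev + (q1 * lam).sum(axis=1) - ctgt_a)
    obj = obj + np.abs(cum_b_prev + (q2 * lam).sum(axis=1) - ctgt_b)
    return obj


def _search_axis(solver, cand, prev, other_seg, L, p_a, p_b, lam, axis, budget):
    """Two-stage (coarse then local) direct search over one boundary's endpoint."""
    coarse_idx = np.unique(np.linspace(0, cand.size - 1, 21).astype(int))

    def evaluate(idx):
        seg = _linear_segments(prev, cand[idx], L)
        other = np.broadcast_to(other_seg, seg.shape)
        if axis == "upper":
            q1, q2 = solver.segment_densities(seg, other)
        else:
            q1, q2 = solver.segment_densities(other, seg)
        return _segment_objective(q1, q2, p_a, p_b, lam, budget), seg

    obj, _ = evaluate(coarse_idx)
    best = coarse_idx[int(np.argmin(obj))]
    lo, hi = max(0, best - 5), min(cand.size, best + 6)
    fine_idx = np.arange(lo, hi)
    obj, segs = evaluate(fine_idx)
    j = int(np.argmin(obj))
    return cand[fine_idx[j]], segs[j], float(obj[j])


def piecewise_refine(
    partial: InversionResult,
    target: ChoiceRTDistribution,
    ev: EvidenceDistribution,
    cfg: InversionConfig,
    guide_upper: np.ndarray | None = None,
) -> InversionResult:
    """Replace the boundary tail beyond the critical step by piecewise-linear fits.

    Steps after ``partial.main_until`` are grouped into connected segments of
    ``cfg.refine_segment_len`` steps.  For each segment the endpoint levels of
    the two boundaries are chosen by direct search (coordinate descent over
    the candidate grid, two sweeps, interior steps linearly interpolated) to
    minimize the summed absolute deviation between regenerated and target
    per-step probabilities over the segment; the point-wise values are kept
    whenever they already score better, so the total objective never
    increases.  If ``partial`` already meets the tolerance at every step
    (``main_until`` equals the horizon) the input is returned unchanged.

    For symmetric results an optional ``guide_upper`` trajectory (one level
    per step over the full horizon) is entered as an additional candidate in
    every segment.  The greedy left-to-right search is myopic — under a
    symmetry constraint with drifted evidence it can satisfy the large-mass
    boundary early and then retreat, stranding the other side's mass — and a
    globally-shaped guide (e.g. the symmetrized unconstrained solution) lets
    each segment escape that trap when the guide scores better.
    """
    tgt, mass, last_pos, horizon = _prepare_target(target, ev, cfg)
    horizon = min(horizon, partial.bounds.n_steps)
    m = partial.main_until
    if m >= horizon:
        return partial
    lam = cfg.step
    solver = VolterraSolver(ev, partial.bounds.start_upper, partial.bounds.start_lower, DiffusionState())
    for k in range(m):
        solver.commit(partial.bounds.upper[k], partial.bounds.lower[k])
    cand_up = cfg.candidate_grid("upper")
    cand_lo = cfg.candidate_grid("lower")
    symmetric = partial.symmetric
    ctgt_a = np.cumsum(tgt.pmf_upper)
    ctgt_b = np.cumsum(tgt.pmf_lower)
    cum_a = float(solver._g1[: solver.n].sum()) * lam
    cum_b = float(solver._g2[: solver.n].sum()) * lam
    refined_obj = 0.0
    unrefined_obj = 0.0
    start = m
    while start < horizon:
        L = min(cfg.refine_segment_len, horizon - start)
        p_a = tgt.pmf_upper[start : start + L]
        p_b = tgt.pmf_lower[start : start + L]
        budget = (cum_a, cum_b, ctgt_a[start + L - 1], ctgt_b[start + L - 1])
        prev1, prev2 = solver._prev()
        # objective of the point-wise values, evaluated in the current context
        seg1_pw = partial.bounds.upper[start : start + L][None, :]
        seg2_pw = partial.bounds.lower[start : start + L][None, :]
        q1, q2 = solver.segment_densities(seg1_pw, seg2_pw)
        obj_pw = float(_segment_objective(q1, q2, p_a, p_b, lam, budget)[0])
        if symmetric:
            e1 = prev1
            seg_best = None
            obj_best = np.inf
            extra = None
            if guide_upper is not None:
                extra = guide_upper[start : start + L]
                if extra.size < L:
                    extra = np.pad(extra, (0, L - extra.size), mode="edge")
            for stage in ("coarse", "fine", "guide"):
                if stage == "coarse":
                    idx = np.unique(np.linspace(0, cand_up.size - 1, 21).astype(int))
                    seg = _linear_segments(prev1, cand_up[idx], L)
                elif stage == "fine":
                    j0 = int(np.argmin(np.abs(cand_up - e1)))
                    idx = np.arange(max(0, j0 - 5), min(cand_up.size, j0 + 6))
                    seg = _linear_segments(prev1, cand_up[idx], L)
                else:
                    if extra is None:
                        continue
                    seg = extra[None, :]
                q1, q2 = solver.segment_densities(seg, -seg)
                obj = _segment_objective(q1, q2, p_a, p_b, lam, budget)
                j = int(np.argmin(obj))
                if obj[j] < obj_best:
                    obj_best, e1, seg_best = float(obj[j]), seg[j][-1], seg[j]
            best1, best2, obj_ref = seg_best, -seg_best, obj_best
        else:
            seg1 = seg1_pw[0].copy()
            seg2 = seg2_pw[0].copy()
            obj_ref = obj_pw
            best1, best2 = seg1, seg2
            for _sweep in range(2):
                _e1, seg1_new, o = _search_axis(solver, cand_up, prev1, best2, L, p_a, p_b, lam, "upper", budget)
                if o <= obj_ref:
                    obj_ref, best1 = o, seg1_new
                _e2, seg2_new, o = _search_axis(solver, cand_lo, prev2, best1, L, p_a, p_b, lam, "lower", budget)
                if o <= obj_ref:
                    obj_ref, best2 = o, seg2_new
        if obj_pw <= obj_ref:
            best1, best2, obj_ref = seg1_pw[0], seg2_pw[0], obj_pw
        refined_obj += obj_ref
        unrefined_obj += obj_pw
        q1, q2 = solver.segment_densities(best1[None, :], best2[None, :])
        for j in range(L):
            solver.commit(best1[j], best2[j], float(q1[0, j]), float(q2[0, j]))
        cum_a += float(q1.sum()) * lam
        cum_b += float(q2.sum()) * lam
        start += L
    bounds = BoundaryPair(
        solver.upper_values, solver.lower_values, partial.bounds.start_upper, partial.bounds.start_lower, lam
    )
    achieved = ChoiceRTDistribution(
        np.clip(solver.g_upper * lam, 0.0, None), np.clip(solver.g_lower * lam, 0.0, None), lam
    )
    residuals = np.abs(achieved.pmf_upper - tgt.pmf_upper[:horizon]) + np.abs(
        achieved.pmf_lower - tgt.pmf_lower[:horizon]
    )
    return InversionResult(
        bounds=bounds,
        main_until=m,
        residuals=residuals,
        achieved=achieved,
        symmetric=symmetric,
        refined=True,
        converged=refined_obj <= unrefined_obj + 1e-12,
        target_mass=mass,
        last_target_step=last_pos,
        distance=boundary_residual(achieved, ChoiceRTDistribution(tgt.pmf_upper[:horizon], tgt.pmf_lower[:horizon], lam)),
    )
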