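"""Forward first-passage-time machinery for the Wiener accrual process.

A two-choice diffusion model accumulates Gaussian evidence ``N(mu, sigma)``
every ``step`` seconds; in the continuum limit the tally is a Wiener process
with drift ``xi = mu/step`` and infinitesimal variance ``s^2 = sigma^2/step``.
A decision is made when the tally first reaches the upper boundary ``a_A(t)``
(choice A) or the lower boundary ``a_B(t)`` (choice B).

The first-passage densities ``g_A``, ``g_B`` through arbitrary (discretized)
time-varying boundaries satisfy a pair of coupled Volterra integral equations
linking them to the free transition density.  The raw (first-kind) equations
have a singular kernel as ``tau -> t``; rewriting them with the
singularity-removed kernel :func:`psi_kernel` produces a second-kind system
whose kernel vanishes on the diagonal for smooth boundaries, so a simple
composite trapezoidal rule on the step grid yields a stable explicit
recursion (:class:`VolterraSolver`, :func:`solve_fpt`).

Two independent oracles are provided: the classical infinite-series solution
for constant symmetric boundaries (:func:`analytic_fpt_constant`) and a
Monte Carlo path simulator (:func:`simulate_paths`).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .types import BoundaryPair, ChoiceRTDistribution, DiffusionState, EvidenceDistribution

__all__ = [
    "FPTNumericalError",
    "transition_density",
    "free_cdf",
    "psi_kernel",
    "VolterraSolver",
    "solve_fpt",
    "analytic_fpt_constant",
    "constant_boundary_p_upper",
    "simulate_paths",
    "simulate_first_passages",
    "ks_distance",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


class FPTNumericalError(RuntimeError):
    """Raised when the Volterra recursion produces non-finite densities."""


# ---------------------------------------------------------------------------
# transition density and kernel
# ---------------------------------------------------------------------------

def _check_time_order(t, tau) -> np.ndarray:
    dt = np.asarray(t, dtype=float) - np.asarray(tau, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("transition density requires t > tau")
    return dt


def transition_density(x, t, y, tau, ev: EvidenceDistribution):
    """Free (no-boundary) Gaussian transition density ``f(x, t | y, tau)``.

    The density of the Wiener tally being at ``x`` at time ``t`` given it was
    at ``y`` at the earlier time ``tau``:

    ``f = exp(-(x - y - xi*(t-tau))^2 / (2 s^2 (t-tau))) / sqrt(2 pi s^2 (t-tau))``

    All arguments broadcast; ``t > tau`` is required.
    """
    dt = _check_time_order(t, tau)
    var = ev.diffusion_var * dt
    z = np.asarray(x, dtype=float) - np.asarray(y, dtype=float) - ev.drift * dt
    return np.exp(-(z**2) / (2.0 * var)) / (_SQRT2PI * np.sqrt(var))


def free_cdf(x, t, y, tau, ev: EvidenceDistribution):
    """Free CDF ``F(x, t | y, tau)``: probability the unbounded tally is <= x."""
    from scipy.stats import norm

    dt = _check_time_order(t, tau)
    var = ev.diffusion_var * dt
    z = np.asarray(x, dtype=float) - np.asarray(y, dtype=float) - ev.drift * dt
    return norm.cdf(z / np.sqrt(var))


def psi_kernel(a_val, a_deriv, t, y, tau, ev: EvidenceDistribution):
    """Singularity-removed Volterra kernel for a boundary point.

    ``Psi(a(t), t | y, tau) = f(a(t), t | y, tau)/2 * (a'(t) - (a(t) - y)/(t - tau))``

    For a smooth boundary approached along its own graph (``y = a(tau)``,
    ``tau -> t``) the bracket vanishes at the same rate that ``f`` diverges,
    so the kernel stays bounded (and tends to zero), which is what makes the
    second-kind recursion well behaved.
    """
    dt = _check_time_order(t, tau)
    f = transition_density(a_val, t, y, tau, ev)
    return 0.5 * f * (np.asarray(a_deriv, dtype=float) - (np.asarray(a_val, dtype=float) - np.asarray(y, dtype=float)) / dt)


# ---------------------------------------------------------------------------
# stepwise Volterra solver
# ---------------------------------------------------------------------------

class VolterraSolver:
    """Explicit stepwise solver for the coupled second-kind Volterra system.

    The solver maintains the committed history of boundary values and
    first-passage densities ``g_A(t_k)``, ``g_B(t_k)`` on the grid
    ``t_k = t0 + k*step`` and can (a) extend the solution one step with given
    boundary values (:meth:`commit`), (b) evaluate the densities the *next*
    step would have for whole arrays of candidate boundary levels
    (:meth:`candidate_densities`) — the workhorse of the grid-search
    inversion — and (c) evaluate short trial segments without committing
    (:meth:`segment_densities`) for the piecewise-linear corrective fit.

    Quadrature is the composite trapezoidal rule on the step grid; both
    endpoint weights multiply values that vanish (``g = 0`` at ``t0`` and the
    diagonal kernel limit is zero for smooth boundaries), so the recursion is
    explicit.
    """

    def __init__(
        self,
        ev: EvidenceDistribution,
        start_upper: float,
        start_lower: float,
        state: DiffusionState | None = None,
    ) -> None:
        if state is None:
            state = DiffusionState()
        if not (start_lower < state.x0 < start_upper):
            raise ValueError("initial state must lie strictly between the starting boundaries")
        self.ev = ev
        self.state = state
        self.step = ev.step
        self.start_upper = float(start_upper)
        self.start_lower = float(start_lower)
        cap = 64
        self._t = np.empty(cap)
        self._a1 = np.empty(cap)
        self._a2 = np.empty(cap)
        self._g1 = np.empty(cap)
        self._g2 = np.empty(cap)
        self.n = 0

    # -- bookkeeping --------------------------------------------------------
    def _grow(self) -> None:
        if self.n == self._t.size:
            for name in ("_t", "_a1", "_a2", "_g1", "_g2"):
                arr = getattr(self, name)
                new = np.empty(arr.size * 2)
                new[: arr.size] = arr
                setattr(self, name, new)

    @property
    def g_upper(self) -> np.ndarray:
        return self._g1[: self.n].copy()

    @property
    def g_lower(self) -> np.ndarray:
        return self._g2[: self.n].copy()

    @property
    def upper_values(self) -> np.ndarray:
        return self._a1[: self.n].copy()

    @property
    def lower_values(self) -> np.ndarray:
        return self._a2[: self.n].copy()

    def _prev(self) -> tuple[float, float]:
        if self.n == 0:
            return self.start_upper, self.start_lower
        return self._a1[self.n - 1], self._a2[self.n - 1]

    # -- kernel evaluation --------------------------------------------------
    def _psi_vs_history(self, c: np.ndarray, deriv: np.ndarray, t_n: float, y: np.ndarray, t_hist: np.ndarray) -> np.ndarray:
        """Kernel matrix Psi(c, t_n | y_k, t_k), shape (len(c), len(y))."""
        ev = self.ev
        dt = t_n - t_hist  # (m,) all positive
        dx = c[:, None] - y[None, :] - ev.drift * dt[None, :]
        var = ev.diffusion_var * dt
        f = np.exp(-(dx**2) / (2.0 * var[None, :])) / (_SQRT2PI * np.sqrt(var)[None, :])
        return 0.5 * f * (deriv[:, None] - (c[:, None] - y[None, :]) / dt[None, :])

    def _initial_term(self, c: np.ndarray, deriv: np.ndarray, t_n: float) -> np.ndarray:
        ev, st = self.ev, self.state
        dt = t_n - st.t0
        var = ev.diffusion_var * dt
        dx = c - st.x0 - ev.drift * dt
        f = np.exp(-(dx**2) / (2.0 * var)) / (_SQRT2PI * math.sqrt(var))
        return 0.5 * f * (deriv - (c - st.x0) / dt)

    # -- public stepping API ------------------------------------------------
    def next_time(self) -> float:
        return self.state.t0 + (self.n + 1) * self.step

    def candidate_densities(self, cand_upper, cand_lower) -> tuple[np.ndarray, np.ndarray]:
        """First-passage densities at the next step for candidate boundary levels.

        ``cand_upper`` and ``cand_lower`` are arrays of hypothetical values of
        ``a_A`` and ``a_B`` at the next grid time; the returned ``(q_A, q_B)``
        give, elementwise, the density each candidate would produce given the
        committed history.  The two returned arrays are independent (the
        candidate on one boundary does not enter the other's density at the
        same step, only at later ones).
        """
        c1 = np.atleast_1d(np.asarray(cand_upper, dtype=float))
        c2 = np.atleast_1d(np.asarray(cand_lower, dtype=float))
        t_n = self.next_time()
        prev1, prev2 = self._prev()
        d1 = (c1 - prev1) / self.step
        d2 = (c2 - prev2) / self.step
        q1 = -2.0 * self._initial_term(c1, d1, t_n)
        q2 = 2.0 * self._initial_term(c2, d2, t_n)
        if self.n > 0:
            m = self.n
            t_hist = self._t[:m]
            a1_h, a2_h = self._a1[:m], self._a2[:m]
            g1_h, g2_h = self._g1[:m], self._g2[:m]
            k11 = self._psi_vs_history(c1, d1, t_n, a1_h, t_hist)
            k12 = self._psi_vs_history(c1, d1, t_n, a2_h, t_hist)
            k21 = self._psi_vs_history(c2, d2, t_n, a1_h, t_hist)
            k22 = self._psi_vs_history(c2, d2, t_n, a2_h, t_hist)
            q1 = q1 + 2.0 * self.step * (k11 @ g1_h + k12 @ g2_h)
            q2 = q2 - 2.0 * self.step * (k21 @ g1_h + k22 @ g2_h)
        return q1, q2

    def commit(self, a_upper: float, a_lower: float, g_upper: float | None = None, g_lower: float | None = None) -> tuple[float, float]:
        """Fix the boundary values at the next step and record its densities.

        ``g_upper``/``g_lower`` may be supplied (e.g. from a previous
        :meth:`candidate_densities` call) to avoid recomputation.
        """
        if g_upper is None or g_lower is None:
            q1, q2 = self.candidate_densities([a_upper], [a_lower])
            g_upper, g_lower = float(q1[0]), float(q2[0])
        self._grow()
        i = self.n
        self._t[i] = self.next_time()
        self._a1[i] = a_upper
        self._a2[i] = a_lower
        self._g1[i] = g_upper
        self._g2[i] = g_lower
        self.n += 1
        return g_upper, g_lower

    def segment_densities(self, seg_upper, seg_lower) -> tuple[np.ndarray, np.ndarray]:
        """Densities over a trial segment of future steps, without committing.

        ``seg_upper``/``seg_lower`` have shape ``(S, L)``: ``S`` candidate
        boundary continuations, each ``L`` steps long.  Returns ``(q_A, q_B)``
        of the same shape.  Within-segment coupling is handled exactly: the
        density of segment step ``j`` uses the candidate's own densities at
        earlier segment steps.
        """
        seg1 = np.atleast_2d(np.asarray(seg_upper, dtype=float))
        seg2 = np.atleast_2d(np.asarray(seg_lower, dtype=float))
        if seg1.shape != seg2.shape:
            raise ValueError("segment arrays must have identical shapes")
        S, L = seg1.shape
        m = self.n
        t_hist = self._t[:m]
        a1_h, a2_h = self._a1[:m], self._a2[:m]
        g1_h, g2_h = self._g1[:m], self._g2[:m]
        prev1, prev2 = self._prev()
        prev1 = np.full(S, prev1)
        prev2 = np.full(S, prev2)
        q1s = np.empty((S, L))
        q2s = np.empty((S, L))
        seg_times = self.state.t0 + (m + 1 + np.arange(L)) * self.step
        for j in range(L):
            t_n = seg_times[j]
            c1, c2 = seg1[:, j], seg2[:, j]
            d1 = (c1 - prev1) / self.step
            d2 = (c2 - prev2) / self.step
            q1 = -2.0 * self._initial_term(c1, d1, t_n)
            q2 = 2.0 * self._initial_term(c2, d2, t_n)
            acc1 = np.zeros(S)
            acc2 = np.zeros(S)
            if m > 0:
                acc1 += self._psi_vs_history(c1, d1, t_n, a1_h, t_hist) @ g1_h
                acc1 += self._psi_vs_history(c1, d1, t_n, a2_h, t_hist) @ g2_h
                acc2 += self._psi_vs_history(c2, d2, t_n, a1_h, t_hist) @ g1_h
                acc2 += self._psi_vs_history(c2, d2, t_n, a2_h, t_hist) @ g2_h
            for jj in range(j):
                dtj = t_n - seg_times[jj]
                for (c, d, acc) in ((c1, d1, acc1), (c2, d2, acc2)):
                    for (y, g) in ((seg1[:, jj], q1s[:, jj]), (seg2[:, jj], q2s[:, jj])):
                        var = self.ev.diffusion_var * dtj
                        dx = c - y - self.ev.drift * dtj
                        f = np.exp(-(dx**2) / (2.0 * var)) / (_SQRT2PI * math.sqrt(var))
                        acc += 0.5 * f * (d - (c - y) / dtj) * g
            q1s[:, j] = q1 + 2.0 * self.step * acc1
            q2s[:, j] = q2 - 2.0 * self.step * acc2
            prev1, prev2 = c1, c2
        return q1s, q2s


def solve_fpt(
    bounds: BoundaryPair,
    ev: EvidenceDistribution,
    state: DiffusionState | None = None,
    n_steps: int | None = None,
) -> ChoiceRTDistribution:
    """Map ``(mu, sigma, a_A, a_B)`` to the choice/RT distribution.

    Steps the coupled second-kind Volterra system over the boundary grid and
    returns the defective per-step probabilities ``P_X(n) = g_X(n*step)*step``.

    If the boundaries touch (``upper <= lower``) before the requested horizon
    the process is truncated there with a warning and the not-yet-absorbed
    mass is split equally between the two (coincident) boundaries.
    """
    if not math.isclose(bounds.step, ev.step, rel_tol=1e-12):
        raise ValueError("bounds and evidence distribution must share the same step")
    if state is None:
        state = DiffusionState()
    N = bounds.n_steps if n_steps is None else int(n_steps)
    if N > bounds.n_steps:
        raise ValueError("n_steps exceeds the boundary grid")
    touched = bounds.first_crossing()
    forced = False
    if touched is not None and touched <= N:
        warnings.warn(
            f"boundaries touch at step {touched}; truncating and forcing absorption",
            RuntimeWarning,
            stacklevel=2,
        )
        N = touched - 1
        forced = True
    solver = VolterraSolver(ev, bounds.start_upper, bounds.start_lower, state)
    for i in range(N):
        solver.commit(bounds.upper[i], bounds.lower[i])
    g1, g2 = solver.g_upper, solver.g_lower
    if not (np.isfinite(g1).all() and np.isfinite(g2).all()):
        raise FPTNumericalError("Volterra recursion produced non-finite densities")
    pmf_u = np.clip(g1 * ev.step, 0.0, None)
    pmf_l = np.clip(g2 * ev.step, 0.0, None)
    if forced:
        # boundaries coincide: split the surviving mass equally at the touch step
        resid = max(0.0, 1.0 - pmf_u.sum() - pmf_l.sum())
        pmf_u = np.append(pmf_u, resid / 2.0)
        pmf_l = np.append(pmf_l, resid / 2.0)
    return ChoiceRTDistribution(pmf_u, pmf_l, ev.step)


# ---------------------------------------------------------------------------
# constant-boundary analytic oracle
# ---------------------------------------------------------------------------

def constant_boundary_p_upper(a: float, ev: EvidenceDistribution, x0: float = 0.0) -> float:
    """Closed-form absorption probability at ``+a`` for barriers ``+-a``.

    For a Wiener process with drift ``v`` and variance ``s^2`` started at
    ``x0`` between barriers ``-a`` and ``+a``:
    ``P(upper) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v L / s^2))`` with
    ``z = x0 + a`` and ``L = 2a`` (limit ``z / L`` when ``v = 0``).
    """
    if not a > 0:
        raise ValueError("a must be > 0")
    v, s2 = ev.drift, ev.diffusion_var
    z, L = x0 + a, 2.0 * a
    if v == 0:
        return z / L
    r = 2.0 * v / s2
    return float(np.expm1(-r * z) / np.expm1(-r * L))


def analytic_fpt_constant(
    a: float,
    ev: EvidenceDistribution,
    n_steps: int,
    tol: float = 1e-12,
) -> ChoiceRTDistribution:
    """Series solution for constant boundaries at ``+-a``, start 0.

    Uses the classical large-time eigenfunction expansion of the defective
    first-passage densities of a drifted Wiener process between two absorbing
    barriers, truncated once the envelope of additional terms falls below
    ``tol``.  Returned per-step probabilities follow the same right-endpoint
    convention as :func:`solve_fpt` (``P_n = g(n*step)*step``).
    """
    if not a > 0:
        raise ValueError("a must be > 0")
    v, s2 = ev.drift, ev.diffusion_var
    L, z = 2.0 * a, a  # measured from the lower barrier; start midway
    t = ev.step * np.arange(1, n_steps + 1)
    t_min = t[0]
    # series term k decays like k * exp(-k^2 pi^2 s2 t_min / (2 L^2)):
    # choose k_max so the first neglected envelope is below tol
    decay = math.pi**2 * s2 * t_min / (2.0 * L**2)
    k_max = int(math.ceil(math.sqrt(max(-math.log(tol), 1.0) / decay))) + 5
    k_max = min(max(k_max, 10), 100_000)
    k = np.arange(1, k_max + 1)
    lam = 0.5 * (v**2 / s2 + (k**2) * (math.pi**2) * s2 / L**2)  # (K,)
    decay_t = np.exp(-np.outer(lam, t))  # (K, N)
    pref = math.pi * s2 / L**2
    g_lower = pref * math.exp(-z * v / s2) * ((k * np.sin(k * math.pi * z / L)) @ decay_t)
    g_upper = pref * math.exp((L - z) * v / s2) * ((k * np.sin(k * math.pi * (L - z) / L)) @ decay_t)
    # early times suffer alternating-sign cancellation; clip the tiny negatives
    g_lower = np.clip(g_lower, 0.0, None)
    g_upper = np.clip(g_upper, 0.0, None)
    return ChoiceRTDistribution(g_upper * ev.step, g_lower * ev.step, ev.step)


# ---------------------------------------------------------------------------
# Monte Carlo oracle
# ---------------------------------------------------------------------------

def simulate_first_passages(
    bounds: BoundaryPair,
    ev: EvidenceDistribution,
    n_trials: int,
    seed: int,
    x0: float = 0.0,
    bridge: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level first passages: returns ``(steps, choices)``.

    ``steps[i]`` is the 1-based absorption step of trial ``i`` (0 when the
    trial survived the horizon — an overflow) and ``choices[i]`` is +1 for the
    upper boundary, -1 for the lower, 0 for overflow.

    With ``bridge=True`` (default) a Brownian-bridge correction accounts for
    crossings *between* grid points, making the simulator an unbiased (to
    within boundary-linearization error) sampler of the continuous-time
    first-passage problem.  With ``bridge=False`` the trial is absorbed only
    when the sampled tally itself lies outside the boundaries, i.e. the raw
    discrete random walk.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    N = bounds.n_steps
    steps = np.zeros(n_trials, dtype=np.int64)
    choices = np.zeros(n_trials, dtype=np.int8)
    idx = np.arange(n_trials)
    x = np.full(n_trials, float(x0))
    prev_u = np.full(n_trials, bounds.start_upper)
    prev_l = np.full(n_trials, bounds.start_lower)
    s2step = ev.sigma**2  # variance accrued per step = s^2 * step
    for n in range(1, N + 1):
        if idx.size == 0:
            break
        u, l = bounds.upper[n - 1], bounds.lower[n - 1]
        x_new = x + rng.normal(ev.mu, ev.sigma, size=idx.size)
        hit_up = x_new >= u
        hit_lo = x_new <= l
        if bridge:
            alive = ~(hit_up | hit_lo)
            if alive.any():
                xa, xb = x[alive], x_new[alive]
                pu = np.exp(-2.0 * (prev_u[alive] - xa) * (u - xb) / s2step)
                pl = np.exp(-2.0 * (xa - prev_l[alive]) * (xb - l) / s2step)
                draw = rng.random((2, xa.size))
                bu = draw[0] < pu
                bl = (~bu) & (draw[1] < pl)
                sub_up = np.zeros_like(hit_up)
                sub_lo = np.zeros_like(hit_lo)
                sub_up[np.nonzero(alive)[0][bu]] = True
                sub_lo[np.nonzero(alive)[0][bl]] = True
                hit_up = hit_up | sub_up
                hit_lo = hit_lo | sub_lo
        done = hit_up | hit_lo
        if done.any():
            steps[idx[hit_up]] = n
            choices[idx[hit_up]] = 1
            steps[idx[hit_lo & ~hit_up]] = n
            choices[idx[hit_lo & ~hit_up]] = -1
            keep = ~done
            idx = idx[keep]
            x = x_new[keep]
        else:
            x = x_new
        prev_u = np.full(idx.size, u)
        prev_l = np.full(idx.size, l)
    return steps, choices


def simulate_paths(
    bounds: BoundaryPair,
    ev: EvidenceDistribution,
    n_trials: int,
    seed: int,
    x0: float = 0.0,
    bridge: bool = True,
) -> ChoiceRTDistribution:
    """Empirical choice/RT distribution from Monte Carlo paths.

    Trials that survive the horizon are reported in the distribution's
    ``overflow`` bucket.  Reproducible given ``seed``.
    """
    steps, choices = simulate_first_passages(bounds, ev, n_trials, seed, x0=x0, bridge=bridge)
    N = bounds.n_steps
    pmf_u = np.bincount(steps[choices == 1], minlength=N + 1)[1:] / n_trials
    pmf_l = np.bincount(steps[choices == -1], minlength=N + 1)[1:] / n_trials
    overflow = float((choices == 0).sum()) / n_trials
    return ChoiceRTDistribution(pmf_u, pmf_l, ev.step, overflow=overflow)


# ---------------------------------------------------------------------------
# comparison helper
# ---------------------------------------------------------------------------

def ks_distance(binned: ChoiceRTDistribution, pointwise: ChoiceRTDistribution, side: str = "upper") -> float:
    """Kolmogorov–Smirnov distance between conditional RT distributions.

    ``binned`` holds genuine per-bin masses (e.g. Monte Carlo counts), while
    ``pointwise`` holds point densities times the step (the solver/series
    convention).  The pointwise cumulative is therefore evaluated with the
    trapezoidal half-step correction ``F(t_n) ~= sum_{k<=n} P_k - P_n/2`` so
    the two sides estimate the same continuous CDF.
    """
    if binned.n_steps != pointwise.n_steps or not math.isclose(binned.step, pointwise.step):
        raise ValueError("distributions must share the same grid")
    pb = binned._side(side)
    pp = pointwise._side(side)
    cb = np.cumsum(pb) / pb.sum()
    cp = np.cumsum(pp) - 0.5 * pp
    cp = cp / (np.sum(pp))
    return float(np.abs(cb - cp).max())
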