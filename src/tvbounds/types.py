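"""Core domain containers for two-choice sequential-sampling models.

The objects here describe the three ingredients of the forward and inverse
first-passage-time problems:

* :class:`EvidenceDistribution` — the Gaussian evidence sampled once per
  time step, together with the step duration, from which the continuous-time
  drift and diffusion coefficient are derived.
* :class:`BoundaryPair` — a pair of discretized, possibly time-varying
  absorbing boundaries.
* :class:`ChoiceRTDistribution` — the (defective) per-step probabilities of
  each choice, i.e. the joint distribution of choice and response time on a
  regular time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EvidenceDistribution",
    "DiffusionState",
    "BoundaryPair",
    "ChoiceRTDistribution",
]


@dataclass(frozen=True)
class EvidenceDistribution:
    """Per-step Gaussian evidence ``N(mu, sigma)`` sampled every ``step`` seconds.

    In the diffusion limit the accrual process is a Wiener process with drift
    ``xi = mu / step`` and infinitesimal variance ``s^2 = sigma^2 / step``.

    Parameters
    ----------
    mu : float
        Mean evidence per sample (unitless evidence units).
    sigma : float
        Standard deviation of the evidence per sample; must be positive.
    step : float
        Duration of one sampling step, in seconds; must be positive.
    """

    mu: float
    sigma: float
    step: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.step > 0):
            raise ValueError(f"step must be > 0, got {self.step}")
        if not (math.isfinite(self.drift) and math.isfinite(self.diffusion_var)):
            raise ValueError("derived drift/diffusion coefficients are not finite")

    @property
    def drift(self) -> float:
        """Drift rate ``xi = mu / step`` of the equivalent Wiener process."""
        return self.mu / self.step

    @property
    def diffusion_var(self) -> float:
        """Infinitesimal variance ``s^2 = sigma^2 / step``."""
        return self.sigma**2 / self.step

    @property
    def diffusion_sd(self) -> float:
        """Infinitesimal standard deviation ``s``."""
        return math.sqrt(self.diffusion_var)

    def scaled(self, c: float) -> "EvidenceDistribution":
        """Return a copy with the evidence scale multiplied by ``c`` (sigma only)."""
        return EvidenceDistribution(self.mu * c, self.sigma * c, self.step)


@dataclass(frozen=True)
class DiffusionState:
    """Initial condition of the accrual process: tally ``x0`` at time ``t0``."""

    x0: float = 0.0
    t0: float = 0.0


class BoundaryPair:
    """Discretized absorbing boundaries ``a_A(n)`` (upper) and ``a_B(n)`` (lower).

    Values are stored on the grid ``t_n = n * step`` for ``n = 1..N``
    (1-based step convention), with the values at ``n = 0`` kept
    separately as ``start_upper`` / ``start_lower`` so that the backward
    finite-difference derivative ``a'(n) = (a(n) - a(n-1)) / step`` is defined
    from the first step onward.
    """

    def __init__(
        self,
        upper: Sequence[float] | np.ndarray,
        lower: Sequence[float] | np.ndarray,
        start_upper: float,
        start_lower: float,
        step: float,
    ) -> None:
        self.upper = np.asarray(upper, dtype=float)
        self.lower = np.asarray(lower, dtype=float)
        if self.upper.ndim != 1 or self.upper.shape != self.lower.shape:
            raise ValueError("upper and lower must be 1-D arrays of equal length")
        if not (step > 0):
            raise ValueError("step must be > 0")
        if not (start_upper > 0 > start_lower):
            raise ValueError(
                f"need start_upper > 0 > start_lower, got {start_upper}, {start_lower}"
            )
        if not (np.isfinite(self.upper).all() and np.isfinite(self.lower).all()):
            raise ValueError("boundary values must be finite")
        self.start_upper = float(start_upper)
        self.start_lower = float(start_lower)
        self.step = float(step)

    # -- geometry -----------------------------------------------------------
    @property
    def n_steps(self) -> int:
        return self.upper.size

    @property
    def times(self) -> np.ndarray:
        """Grid times ``t_n = n * step`` for ``n = 1..N``."""
        return self.step * np.arange(1, self.n_steps + 1)

    @property
    def upper_deriv(self) -> np.ndarray:
        """Backward-difference derivative of the upper boundary at each step."""
        return np.diff(self.upper, prepend=self.start_upper) / self.step

    @property
    def lower_deriv(self) -> np.ndarray:
        return np.diff(self.lower, prepend=self.start_lower) / self.step

    def first_crossing(self) -> int | None:
        """1-based index of the first step where ``upper <= lower``, else None."""
        bad = np.nonzero(self.upper <= self.lower)[0]
        return int(bad[0]) + 1 if bad.size else None

    def scaled(self, c: float) -> "BoundaryPair":
        if not c > 0:
            raise ValueError("scale factor must be positive")
        return BoundaryPair(
            self.upper * c, self.lower * c, self.start_upper * c, self.start_lower * c, self.step
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_functions(
        cls,
        upper: Callable[[np.ndarray], np.ndarray],
        lower: Callable[[np.ndarray], np.ndarray],
        step: float,
        n_steps: int,
    ) -> "BoundaryPair":
        """Sample continuous boundary functions of time on the step grid."""
        t = step * np.arange(1, n_steps + 1)
        return cls(
            np.asarray(upper(t), dtype=float),
            np.asarray(lower(t), dtype=float),
            float(upper(np.asarray(0.0))),
            float(lower(np.asarray(0.0))),
            step,
        )

    @classmethod
    def constant(cls, a_upper: float, a_lower: float, step: float, n_steps: int) -> "BoundaryPair":
        """Flat boundaries at ``a_upper`` and ``a_lower``."""
        return cls(
            np.full(n_steps, float(a_upper)),
            np.full(n_steps, float(a_lower)),
            a_upper,
            a_lower,
            step,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BoundaryPair(n_steps={self.n_steps}, step={self.step}, "
            f"start=({self.start_upper}, {self.start_lower}))"
        )


class ChoiceRTDistribution:
    """Defective per-step choice/RT probabilities ``P_A(n)``, ``P_B(n)``.

    ``pmf_upper[n-1]`` is the probability that the upper boundary (choice A)
    is reached at step ``n`` (time ``n * step``); similarly for ``pmf_lower``.
    The total mass over both choices is at most 1; for a well-chosen horizon
    the residual (truncated) mass is small.  ``overflow`` records mass known
    to lie beyond the horizon (used by simulators).
    """

    #: entries more negative than this raise; larger ones are clipped to zero
    _NEG_TOL = 1e-9

    def __init__(
        self,
        pmf_upper: Sequence[float] | np.ndarray,
        pmf_lower: Sequence[float] | np.ndarray,
        step: float,
        overflow: float = 0.0,
    ) -> None:
        pu = np.asarray(pmf_upper, dtype=float)
        pl = np.asarray(pmf_lower, dtype=float)
        if pu.ndim != 1 or pu.shape != pl.shape:
            raise ValueError("pmf_upper and pmf_lower must be 1-D arrays of equal length")
        if not (step > 0):
            raise ValueError("step must be > 0")
        for name, arr in (("pmf_upper", pu), ("pmf_lower", pl)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")
            if (arr < -self._NEG_TOL).any():
                raise ValueError(f"{name} contains negative probabilities")
        self.pmf_upper = np.clip(pu, 0.0, None)
        self.pmf_lower = np.clip(pl, 0.0, None)
        self.step = float(step)
        self.overflow = float(overflow)

    # -- basic quantities ---------------------------------------------------
    @property
    def n_steps(self) -> int:
        return self.pmf_upper.size

    @property
    def times(self) -> np.ndarray:
        return self.step * np.arange(1, self.n_steps + 1)

    @property
    def mass_upper(self) -> float:
        return float(self.pmf_upper.sum())

    @property
    def mass_lower(self) -> float:
        return float(self.pmf_lower.sum())

    @property
    def total_mass(self) -> float:
        """Captured probability mass (excludes ``overflow``)."""
        return self.mass_upper + self.mass_lower

    @property
    def p_upper(self) -> float:
        """Probability of choosing A, normalized over the captured mass."""
        tot = self.total_mass
        if tot <= 0:
            raise ValueError("distribution has no captured mass")
        return self.mass_upper / tot

    # -- derived summaries --------------------------------------------------
    def _side(self, side: str) -> np.ndarray:
        if side == "upper":
            return self.pmf_upper
        if side == "lower":
            return self.pmf_lower
        raise ValueError("side must be 'upper' or 'lower'")

    def mean_rt(self, side: str) -> float:
        """Mean response time (seconds) conditional on the given choice."""
        p = self._side(side)
        m = p.sum()
        if m <= 0:
            raise ValueError(f"no mass on side {side!r}")
        return float((self.times * p).sum() / m)

    def skewness(self, side: str) -> float:
        """Standardized third central moment of the conditional RT distribution."""
        p = self._side(side)
        m = p.sum()
        mu = (self.times * p).sum() / m
        var = ((self.times - mu) ** 2 * p).sum() / m
        third = ((self.times - mu) ** 3 * p).sum() / m
        return float(third / var**1.5)

    def cumulative(self, side: str) -> np.ndarray:
        return np.cumsum(self._side(side))

    def renormalized(self) -> "ChoiceRTDistribution":
        """Rescale so the captured mass totals exactly 1 (drops overflow)."""
        tot = self.total_mass
        if tot <= 0:
            raise ValueError("cannot renormalize a distribution with zero mass")
        return ChoiceRTDistribution(self.pmf_upper / tot, self.pmf_lower / tot, self.step)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ChoiceRTDistribution(n_steps={self.n_steps}, step={self.step}, "
            f"p_upper={self.p_upper:.4f}, total_mass={self.total_mass:.4f})"
        )
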