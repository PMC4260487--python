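import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tvbounds import BoundaryPair, EvidenceDistribution, solve_fpt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

STEP = 0.01


@pytest.fixture(scope="session")
def ev_drift() -> EvidenceDistribution:
    """Weak-drift evidence: mu=0.01, sigma=0.1 per 10 ms sample."""
    return EvidenceDistribution(0.01, 0.1, STEP)


@pytest.fixture(scope="session")
def ev_zero() -> EvidenceDistribution:
    return EvidenceDistribution(0.0, 0.1, STEP)


@pytest.fixture(scope="session")
def exp_bounds() -> BoundaryPair:
    """Exponentially collapsing boundaries exp(-t), horizon 4.5 s."""
    return BoundaryPair.from_functions(lambda t: np.exp(-t), lambda t: -np.exp(-t), STEP, 450)


@pytest.fixture(scope="session")
def exp_target(exp_bounds, ev_zero):
    """Forward solution of the exp-collapse model (round-trip target)."""
    return solve_fpt(exp_bounds, ev_zero)


@pytest.fixture(scope="session")
def recovery():
    """Shared end-to-end pipeline run: zero-drift collapsing-boundary data
    (10^4 trials, non-decision shift 0.3 s) through shift -> Weibull fit ->
    free-start inversion.  Returns (true_boundary_fn, true_bounds, data,
    result, estimated_shift)."""
    from tvbounds import InversionConfig, fit_boundaries_empirical, shift_rts, synthesize_diffusion_dataset

    ev = EvidenceDistribution(0.0, 0.01, STEP)
    f = lambda t: 0.08 * np.exp(-t / 1.2)
    true_bounds = BoundaryPair.from_functions(lambda t: f(t), lambda t: -f(t), STEP, 300)
    data = synthesize_diffusion_dataset(true_bounds, ev, 10_000, shift=0.3, seed=42)
    result = fit_boundaries_empirical(data, 0.01, InversionConfig(horizon=250))
    _, est_shift = shift_rts(data)
    return f, true_bounds, data, result, est_shift


def mass_region(dist, lo=0.0, hi=0.95):
    """Step slice covering the [lo, hi] quantile band of a distribution's mass."""
    joint = dist.pmf_upper + dist.pmf_lower
    cum = np.cumsum(joint) / joint.sum()
    n_lo = int(np.searchsorted(cum, lo))
    n_hi = int(np.searchsorted(cum, hi)) + 1
    return n_lo, n_hi
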