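import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tvbounds import (
    BoundaryPair,
    EvidenceDistribution,
    analytic_fpt_constant,
    constant_boundary_p_upper,
    ks_distance,
    psi_kernel,
    simulate_paths,
    solve_fpt,
    transition_density,
)

STEP = 0.01


class TestTransitionDensity:
    def test_peak_of_standard_gaussian(self):
        ev = EvidenceDistribution(0.0, 0.1, STEP)  # s = 1
        val = transition_density(0.0, 1.0, 0.0, 0.0, ev)
        assert val == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=1e-12)

    @given(
        x=st.floats(-3, 3),
        y=st.floats(-3, 3),
        dt=st.floats(0.05, 2.0),
    )
    def test_reflection_symmetry_at_zero_drift(self, x, y, dt):
        ev = EvidenceDistribution(0.0, 0.1, STEP)
        a = transition_density(x, dt, y, 0.0, ev)
        b = transition_density(2 * y - x, dt, y, 0.0, ev)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-300)

    def test_quadrature_normalizes_to_one(self):
        ev = EvidenceDistribution(0.03, 0.12, STEP)
        x = np.linspace(-40, 40, 200001)
        f = transition_density(x, 0.7, 0.2, 0.0, ev)
        assert np.trapezoid(f, x) == pytest.approx(1.0, abs=1e-6)

    def test_time_order_enforced(self):
        ev = EvidenceDistribution(0.0, 0.1, STEP)
        with pytest.raises(ValueError):
            transition_density(0.0, 0.5, 0.0, 0.5, ev)
        with pytest.raises(ValueError):
            psi_kernel(1.0, 0.0, 0.3, 0.0, 0.4, ev)


class TestPsiKernel:
    def test_vanishes_on_the_chord(self):
        ev = EvidenceDistribution(0.0, 0.1, STEP)
        a_val, t, tau = 0.8, 1.0, 0.4
        a_deriv = -0.5
        y = a_val - a_deriv * (t - tau)  # chord condition: a' = (a - y)/(t - tau)
        assert psi_kernel(a_val, a_deriv, t, y, tau, ev) == pytest.approx(0.0, abs=1e-15)

    def test_constant_boundary_reduction(self):
        ev = EvidenceDistribution(0.01, 0.1, STEP)
        a, y, t, tau = 1.0, 0.2, 0.9, 0.3
        f = transition_density(a, t, y, tau, ev)
        expected = -f * (a - y) / (2 * (t - tau))
        assert psi_kernel(a, 0.0, t, y, tau, ev) == pytest.approx(expected, rel=1e-12)

    def test_bounded_on_shrinking_gap_along_smooth_boundary(self):
        # tau -> t with y on the boundary graph: the kernel must not diverge
        ev = EvidenceDistribution(0.0, 0.1, STEP)
        a = lambda t: np.exp(-t)
        t = 1.0
        vals = []
        for gap in (0.1, 0.03, 0.01, 0.003, 0.001):
            tau = t - gap
            deriv = -math.exp(-t)
            vals.append(abs(psi_kernel(a(t), deriv, t, a(tau), tau, ev)))
        assert max(vals) < 1.0
        assert vals[-1] < vals[0] + 0.1  # no blow-up as the gap shrinks


class TestForwardSolver:
    def test_zero_drift_symmetry_is_exact(self, ev_zero):
        b = BoundaryPair.constant(1.0, -1.0, STEP, 300)
        d = solve_fpt(b, ev_zero)
        assert np.array_equal(d.pmf_upper, d.pmf_lower)
        assert d.p_upper == pytest.approx(0.5)

    def test_matches_analytic_series_for_constant_boundaries(self, ev_drift):
        n = 500
        num = solve_fpt(BoundaryPair.constant(1.0, -1.0, STEP, n), ev_drift)
        ana = analytic_fpt_constant(1.0, ev_drift, n)
        sup = max(
            np.abs(num.pmf_upper - ana.pmf_upper).max(),
            np.abs(num.pmf_lower - ana.pmf_lower).max(),
        )
        assert sup < 1e-8

    def test_mirror_property_is_exact(self, ev_drift, exp_bounds):
        d = solve_fpt(exp_bounds, ev_drift)
        ev_neg = EvidenceDistribution(-ev_drift.mu, ev_drift.sigma, STEP)
        mirrored = BoundaryPair(
            -exp_bounds.lower, -exp_bounds.upper,
            -exp_bounds.start_lower, -exp_bounds.start_upper, STEP,
        )
        m = solve_fpt(mirrored, ev_neg)
        assert np.array_equal(d.pmf_upper, m.pmf_lower)
        assert np.array_equal(d.pmf_lower, m.pmf_upper)

    def test_scale_invariance(self, ev_drift, exp_bounds):
        d = solve_fpt(exp_bounds, ev_drift)
        c = 3.7
        ev_scaled = EvidenceDistribution(ev_drift.mu * c, ev_drift.sigma * c, STEP)
        s = solve_fpt(exp_bounds.scaled(c), ev_scaled)
        np.testing.assert_allclose(s.pmf_upper, d.pmf_upper, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(s.pmf_lower, d.pmf_lower, rtol=1e-9, atol=1e-15)

    @pytest.mark.parametrize("mu", [0.0, 0.01, 0.05])
    @pytest.mark.parametrize("sigma", [0.1, 0.12])
    def test_conservation_of_mass(self, mu, sigma):
        ev = EvidenceDistribution(mu, sigma, STEP)
        d = solve_fpt(BoundaryPair.constant(1.0, -1.0, STEP, 800), ev)
        assert d.total_mass >= 0.999

    def test_refinement_in_step_size_converges(self):
        # discrepancy to a fine-grid reference shrinks as lambda is halved
        ref_step = 0.0025
        horizon_s = 3.0
        f_up = lambda t: np.exp(-t)
        ref = solve_fpt(
            BoundaryPair.from_functions(f_up, lambda t: -f_up(t), ref_step, int(horizon_s / ref_step)),
            EvidenceDistribution(0.01 * ref_step / STEP, 0.1 * math.sqrt(ref_step / STEP), ref_step),
        )
        g_ref = ref.pmf_upper / ref_step
        discrepancies = []
        for lam in (0.02, 0.01, 0.005):
            ev = EvidenceDistribution(0.01 * lam / STEP, 0.1 * math.sqrt(lam / STEP), lam)
            d = solve_fpt(
                BoundaryPair.from_functions(f_up, lambda t: -f_up(t), lam, int(horizon_s / lam)), ev
            )
            g = d.pmf_upper / lam
            stride = int(lam / ref_step)
            shared = min(g.size, g_ref[stride - 1 :: stride].size)
            discrepancies.append(np.abs(g[:shared] - g_ref[stride - 1 :: stride][:shared]).max())
        assert discrepancies[0] > discrepancies[1] > discrepancies[2]

    def test_step_mismatch_rejected(self, ev_drift):
        with pytest.raises(ValueError):
            solve_fpt(BoundaryPair.constant(1.0, -1.0, 0.02, 10), ev_drift)

    def test_touching_boundaries_truncate_and_split_mass(self, ev_zero):
        up = np.concatenate([np.linspace(0.99, 0.2, 99), [0.0]])
        lo = -up
        lo[-1] = 0.0
        b = BoundaryPair(up, lo, 1.0, -1.0, STEP)
        with pytest.warns(RuntimeWarning):
            d = solve_fpt(b, ev_zero)
        assert d.total_mass == pytest.approx(1.0, abs=1e-6)
        assert d.pmf_upper[-1] == pytest.approx(d.pmf_lower[-1])


class TestAnalyticConstant:
    def test_zero_drift_choice_probability(self, ev_zero):
        d = analytic_fpt_constant(1.0, ev_zero, 600)
        assert d.p_upper == pytest.approx(0.5, abs=1e-9)

    def test_choice_probability_matches_closed_form(self, ev_drift):
        d = analytic_fpt_constant(1.0, ev_drift, 1200)
        assert d.p_upper == pytest.approx(constant_boundary_p_upper(1.0, ev_drift), abs=1e-6)

    def test_invalid_halfwidth_rejected(self, ev_drift):
        with pytest.raises(ValueError):
            analytic_fpt_constant(-1.0, ev_drift, 10)


class TestSimulatePaths:
    def test_same_seed_reproduces(self, ev_zero, exp_bounds):
        a = simulate_paths(exp_bounds, ev_zero, 2000, seed=9)
        b = simulate_paths(exp_bounds, ev_zero, 2000, seed=9)
        assert np.array_equal(a.pmf_upper, b.pmf_upper)
        assert np.array_equal(a.pmf_lower, b.pmf_lower)

    def test_zero_drift_symmetric_choice(self, ev_zero):
        b = BoundaryPair.constant(1.0, -1.0, STEP, 900)
        d = simulate_paths(b, ev_zero, 100_000, seed=2)
        assert abs(d.p_upper - 0.5) < 0.01

    def test_ks_against_analytic_series(self, ev_zero):
        n = 20_000
        b = BoundaryPair.constant(1.0, -1.0, STEP, 900)
        mc = simulate_paths(b, ev_zero, n, seed=5)
        ana = analytic_fpt_constant(1.0, ev_zero, 900)
        assert ks_distance(mc, ana, "upper") < 2.0 / math.sqrt(n // 2)

    def test_raw_walk_is_biased_late(self, ev_zero):
        # without the bridge correction first passages are systematically later
        b = BoundaryPair.constant(1.0, -1.0, STEP, 900)
        bridge = simulate_paths(b, ev_zero, 30_000, seed=3)
        raw = simulate_paths(b, ev_zero, 30_000, seed=3, bridge=False)
        assert raw.mean_rt("upper") > bridge.mean_rt("upper")
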