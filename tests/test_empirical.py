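import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tvbounds import (
    BoundaryPair,
    EvidenceDistribution,
    InversionConfig,
    RTDataset,
    WeibullFit,
    build_targets,
    chi_square_gof,
    fit_boundaries_empirical,
    fit_weibull,
    shift_rts,
    synthesize_diffusion_dataset,
    synthesize_weibull_dataset,
)

from conftest import mass_region


def _dataset(rts, choices=None):
    rts = np.asarray(rts, dtype=float)
    if choices is None:
        choices = np.array(["A"] * rts.size, dtype=object)
    return RTDataset(rt=rts, choice=np.asarray(choices, dtype=object))


class TestShift:
    def test_worked_example(self):
        shifted, shift = shift_rts(_dataset([0.4, 0.5, 0.9]))
        assert shift == pytest.approx(0.399)
        np.testing.assert_allclose(shifted.rt, [0.001, 0.101, 0.501])

    def test_idempotent_up_to_guard(self):
        once, s1 = shift_rts(_dataset([0.4, 0.5, 0.9]))
        twice, s2 = shift_rts(once)
        assert s2 == pytest.approx(0.0)
        np.testing.assert_allclose(twice.rt, once.rt)

    @given(st.lists(st.floats(0.05, 5.0), min_size=2, max_size=50))
    def test_preserves_rank_order(self, rts):
        shifted, _ = shift_rts(_dataset(rts))
        assert np.array_equal(np.argsort(np.asarray(rts), kind="stable"), np.argsort(shifted.rt, kind="stable"))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            RTDataset(rt=np.array([]), choice=np.array([], dtype=object))


class TestWeibullFit:
    def test_parameter_recovery_on_large_sample(self):
        rng = np.random.default_rng(3)
        rts = 0.3 * rng.weibull(2.0, 100_000)
        fit = fit_weibull(_dataset(rts + 1e-12), "A")
        assert abs(fit.shape - 2.0) < 0.05
        assert abs(fit.scale - 0.3) < 0.01

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        rts = 0.3 * rng.weibull(1.7, 2000) + 1e-12
        f1 = fit_weibull(_dataset(rts), "A")
        f2 = fit_weibull(_dataset(3.0 * rts), "A")
        assert f2.shape == pytest.approx(f1.shape, rel=1e-4)
        assert f2.scale == pytest.approx(3.0 * f1.scale, rel=1e-4)

    def test_tiny_sample_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        rts = 0.4 * rng.weibull(2.2, 12) + 1e-12
        fit = fit_weibull(_dataset(rts), "A")
        shapes = np.linspace(0.5, 6.0, 400)
        scales = np.linspace(0.05, 1.5, 400)
        ll = stats.weibull_min.logpdf(
            rts[None, None, :], shapes[:, None, None], scale=scales[None, :, None]
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(fit.shape - shapes[i]) <= shapes[1] - shapes[0]
        assert abs(fit.scale - scales[j]) <= scales[1] - scales[0]

    def test_insufficient_or_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull(_dataset([0.5] * 9), "A")
        with pytest.raises(ValueError):
            fit_weibull(_dataset([0.5] * 20), "A")


class TestBuildTargets:
    def test_mass_telescopes_to_choice_probability(self):
        fa = WeibullFit(shape=2.0, scale=0.3, shift=0.3, choice_prob=0.6, choice="A")
        fb = WeibullFit(shape=1.8, scale=0.35, shift=0.3, choice_prob=0.4, choice="B")
        d = build_targets(fa, fb, 0.01, 300)
        assert d.mass_upper == pytest.approx(0.6 * fa.cdf(3.0), rel=1e-12)
        assert d.mass_lower == pytest.approx(0.4 * fb.cdf(3.0), rel=1e-12)
        assert (d.pmf_upper >= 0).all() and (d.pmf_lower >= 0).all()

    def test_matches_density_quadrature_per_bin(self):
        fa = WeibullFit(shape=2.0, scale=0.3, shift=0.0, choice_prob=1.0, choice="A")
        d = build_targets(fa, fa, 0.01, 200)
        from scipy.integrate import quad

        for n in (1, 30, 120):
            val, _ = quad(
                lambda t: stats.weibull_min.pdf(t, 2.0, scale=0.3), (n - 1) * 0.01, n * 0.01,
                epsabs=1e-13, epsrel=1e-13,
            )
            assert d.pmf_upper[n - 1] == pytest.approx(val, abs=1e-10)

    def test_short_horizon_warns(self):
        fa = WeibullFit(shape=2.0, scale=0.5, shift=0.0, choice_prob=0.5, choice="A")
        with pytest.warns(RuntimeWarning):
            build_targets(fa, fa, 0.01, 20)


class TestChiSquare:
    def test_perfect_decile_fit_gives_zero(self):
        fit = WeibullFit(shape=2.0, scale=0.3, shift=0.0, choice_prob=1.0, choice="A")
        # one observation at the midpoint quantile of each decile bin
        rts = fit.ppf((np.arange(10) + 0.5) / 10.0)
        g = chi_square_gof(_dataset(rts), fit)
        assert g.statistic == 0.0
        assert g.dof == 7
        assert g.p_value == 1.0

    def test_matches_brute_force_oracle(self):
        # independent implementation: explicit bin counting + series expansion
        # of the regularized incomplete gamma for the chi-squared CDF
        def brute(rts, fit, dof=7):
            edges = stats.weibull_min.ppf(np.arange(1, 10) / 10.0, fit.shape, scale=fit.scale)
            counts = [0] * 10
            for r in rts:
                b = 0
                for e in edges:
                    if r > e:
                        b += 1
                counts[b] += 1
            e = len(rts) / 10.0
            statistic = sum((o - e) ** 2 / e for o in counts)
            # P(X > x) for X ~ chi2_dof via the lower incomplete gamma series
            a, x = dof / 2.0, statistic / 2.0
            if x == 0:
                return statistic, 1.0
            term = 1.0 / a
            total = term
            k = 1
            while True:
                term *= x / (a + k)
                total += term
                if term < total * 1e-16 or k > 10_000:
                    break
                k += 1
            lower = total * math.exp(-x + a * math.log(x) - math.lgamma(a))
            return statistic, 1.0 - lower

        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(20, 80))
            fit = WeibullFit(
                shape=float(rng.uniform(1.2, 3.0)),
                scale=float(rng.uniform(0.2, 0.6)),
                shift=0.0,
                choice_prob=1.0,
                choice="A",
            )
            rts = fit.scale * rng.weibull(fit.shape, n) + 1e-12
            ours = chi_square_gof(_dataset(rts), fit)
            stat_b, p_b = brute(rts, fit)
            assert ours.statistic == pytest.approx(stat_b, abs=1e-10)
            assert ours.p_value == pytest.approx(p_b, abs=1e-10)

    def test_too_few_records_rejected(self):
        fit = WeibullFit(shape=2.0, scale=0.3, shift=0.0, choice_prob=1.0, choice="A")
        with pytest.raises(ValueError):
            chi_square_gof(_dataset([0.3] * 9), fit)


class TestSyntheticGenerators:
    def test_weibull_fixture_reproducible_and_shaped(self):
        a = synthesize_weibull_dataset(n_trials=5000, seed=7)
        b = synthesize_weibull_dataset(n_trials=5000, seed=7)
        assert np.array_equal(a.rt, b.rt)
        assert a.rt.min() >= 0.3  # non-decision shift floor
        assert 0.45 < a.choice_prob("A") < 0.55

    def test_diffusion_fixture_rts_include_shift(self, ev_zero):
        ev = EvidenceDistribution(0.0, 0.01, 0.01)
        b = BoundaryPair.constant(0.08, -0.08, 0.01, 300)
        data = synthesize_diffusion_dataset(b, ev, 2000, shift=0.25, seed=1)
        assert data.rt.min() > 0.25
        assert set(np.unique(data.choice)) <= {"A", "B"}


class TestEndToEndRecovery:
    def test_boundary_shape_recovered(self, recovery):
        f, true_bounds, data, result, est_shift = recovery
        offset = est_shift - 0.3  # shift over-estimate: compare on aligned time axes
        n_lo, n_hi = mass_region(result.achieved, 0.025, 0.95)
        t_grid = 0.01 * np.arange(n_lo + 1, n_hi + 1)
        corr = np.corrcoef(f(t_grid + offset), result.bounds.upper[n_lo:n_hi])[0, 1]
        assert corr > 0.9
        assert result.distance <= 0.05
        # start recovery carries the documented smoothing/shift bias (~13% low)
        assert abs(result.bounds.start_upper / f(offset) - 1.0) < 0.2

    def test_symmetric_variant_close_to_unconstrained(self, recovery):
        f, true_bounds, data, result, _ = recovery
        cfg = InversionConfig(horizon=250)
        sym = fit_boundaries_empirical(data, 0.01, cfg, symmetric=True)
        assert sym.distance <= 0.06
        n_lo, n_hi = mass_region(result.achieved, 0.05, 0.90)
        rel = np.abs(sym.bounds.upper[n_lo:n_hi] - result.bounds.upper[n_lo:n_hi])
        assert rel.max() <= 0.15 * result.bounds.start_upper


class TestSubjectOrdering:
    def test_slower_subject_boundaries_descend_later(self):
        cfg = InversionConfig(horizon=220)
        onsets = {}
        for label, scale in (("fast", 0.25), ("slow", 0.45)):
            data = synthesize_weibull_dataset(
                n_trials=4000, scale_a=scale, scale_b=scale * 1.05, shift=0.25, seed=9
            )
            res = fit_boundaries_empirical(data, 0.01, cfg)
            up = res.bounds.upper
            # descent onset: first drop below 20% of the boundary's plateau level
            # (referenced to the max, not the start, because the Weibull head
            # mismatch dents the first few steps)
            onset = int(np.argmax(up < 0.2 * up.max()))
            assert onset > 0  # the boundary does collapse within the horizon
            onsets[label] = onset
        assert onsets["fast"] < onsets["slow"]
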