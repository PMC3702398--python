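"""Latent class models: cell probabilities, EM fit, GOF, random effects."""


import numpy as np
import pytest
from scipy import integrate, special, stats

from callconcord.callset_io import PatternCounts, all_patterns, table1_fixture
from callconcord.latent_class import (
    LcmCIParams,
    LcmREParams,
    ci_covariance,
    ci_loglik,
    ci_pattern_prob,
    fit_ci,
    fit_re,
    lcm_df,
    marginal_rates,
    pearson_gof,
    re_pattern_prob,
)


def brute_force_pattern_prob(eta, fp, fn, pattern):
    """Independent enumeration oracle: explicit sum over the latent class."""
    total = 0.0
    for d, weight in ((0, 1 - eta), (1, eta)):
        p = weight
        for k, y in enumerate(pattern):
            rate = (1 - fn[k]) if d == 1 else fp[k]
            p *= rate if y == 1 else (1 - rate)
        total += p
    return total


def counts_from_probs(params, K, N, rng):
    pats = all_patterns(K)
    probs = [ci_pattern_prob(params, p) for p in pats]
    draw = rng.multinomial(N, probs)
    return PatternCounts(counts=dict(zip(pats, map(int, draw))), K=K)


class TestCiPatternProb:
    def test_perfect_single_caller(self):
        params = LcmCIParams(eta=0.5, fp=np.array([0.0]), fn=np.array([0.0]))
        assert ci_pattern_prob(params, (1,)) == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            K = int(rng.integers(2, 5))
            eta = rng.uniform(0.01, 0.5)
            fp = rng.uniform(0.001, 0.2, K)
            fn = rng.uniform(0.05, 0.5, K)
            params = LcmCIParams(eta=eta, fp=fp, fn=fn)
            pattern = tuple(rng.integers(0, 2, K))
            assert ci_pattern_prob(params, pattern) == pytest.approx(
                brute_force_pattern_prob(eta, fp, fn, pattern), rel=1e-12
            )

    def test_normalization(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 6))
            params = LcmCIParams(
                eta=rng.uniform(0.01, 0.9),
                fp=rng.uniform(0.001, 0.5, K),
                fn=rng.uniform(0.01, 0.9, K),
            )
            total = sum(ci_pattern_prob(params, p) for p in all_patterns(K))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestCiLoglik:
    def test_single_cell_mass(self):
        params = LcmCIParams(eta=0.2, fp=np.array([0.1] * 3), fn=np.array([0.2] * 3))
        pats = all_patterns(3)
        counts = PatternCounts(counts={p: 0 for p in pats} | {(1, 1, 1): 50}, K=3)
        p = ci_pattern_prob(params, (1, 1, 1))
        assert ci_loglik(params, counts) == pytest.approx(50 * np.log(p))

    def test_zero_count_cells_do_not_contribute(self, rng):
        params = LcmCIParams(eta=0.1, fp=rng.uniform(0.01, 0.1, 3), fn=rng.uniform(0.1, 0.4, 3))
        counts = counts_from_probs(params, 3, 500, rng)
        # manual summation oracle
        expected = sum(
            c * np.log(ci_pattern_prob(params, p))
            for p, c in counts.counts.items()
            if c > 0
        )
        assert ci_loglik(params, counts) == pytest.approx(expected, rel=1e-12)


class TestFitCi:
    def test_recovers_known_parameters(self, rng):
        true = LcmCIParams(
            eta=0.05, fp=np.array([0.01, 0.02, 0.005, 0.03]), fn=np.array([0.2, 0.3, 0.1, 0.15])
        )
        counts = counts_from_probs(true, 4, 100_000, rng)
        fit = fit_ci(counts, n_restarts=10, seed=0)
        assert fit.converged
        se = np.sqrt(np.clip(np.diag(ci_covariance(fit.params, counts)), 0, None))
        est = np.concatenate([[fit.params.eta], fit.params.fp, fit.params.fn])
        tru = np.concatenate([[true.eta], true.fp, true.fn])
        assert np.all(np.abs(est - tru) < 4 * se + 1e-4)

    def test_degenerate_two_cell_table(self):
        pats = all_patterns(3)
        counts = PatternCounts(
            counts={p: 0 for p in pats} | {(0, 0, 0): 900, (1, 1, 1): 100}, K=3
        )
        fit = fit_ci(counts, n_restarts=10, seed=0)
        assert fit.params.eta == pytest.approx(0.1, abs=0.01)
        assert np.all(fit.params.fp < 0.01)
        assert np.all(fit.params.fn < 0.01)

    def test_loglik_monotone_over_iterations(self, rng):
        params = LcmCIParams(eta=0.1, fp=rng.uniform(0.01, 0.1, 4), fn=rng.uniform(0.1, 0.4, 4))
        counts = counts_from_probs(params, 4, 5000, rng)
        fit = fit_ci(counts, n_restarts=3, seed=1)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_orientation_constraint(self, rng):
        params = LcmCIParams(eta=0.07, fp=rng.uniform(0.01, 0.05, 4), fn=rng.uniform(0.1, 0.3, 4))
        counts = counts_from_probs(params, 4, 20_000, rng)
        fit = fit_ci(counts, n_restarts=10, seed=2)
        assert fit.params.sens.mean() > fit.params.fp.mean()
        assert fit.params.eta < 0.5

    def test_k2_rejected(self):
        counts = PatternCounts(counts={p: 1 for p in all_patterns(2)}, K=2)
        with pytest.raises(ValueError, match="K >= 3"):
            fit_ci(counts)

    def test_table1_gof_matches_reported_values(self):
        fit = fit_ci(table1_fixture(), n_restarts=20, seed=0)
        assert fit.pearson_chi2 == pytest.approx(11.0, abs=0.5)
        assert fit.df == 6
        assert sum(fit.fitted_counts.values()) == pytest.approx(4439, rel=1e-6)

    def test_loglik_beats_shared_rate_grid_oracle(self, rng):
        """On K=3 tables the MLE dominates a dense grid with shared rates."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            true = LcmCIParams(
                eta=r.uniform(0.05, 0.3), fp=r.uniform(0.01, 0.1, 3), fn=r.uniform(0.1, 0.4, 3)
            )
            counts = counts_from_probs(true, 3, 2000, r)
            fit = fit_ci(counts, n_restarts=10, seed=0)
            pats, n = counts.as_arrays()
            s = pats.sum(axis=1)
            grid = np.arange(0.02, 0.99, 0.02)
            eta_g, fp_g, fn_g = np.meshgrid(grid, grid, grid, indexing="ij")
            ll = np.zeros_like(eta_g)
            for si, cnt in zip(s, n):
                if cnt == 0:
                    continue
                p = (1 - eta_g) * fp_g**si * (1 - fp_g) ** (3 - si) + eta_g * (
                    1 - fn_g
                ) ** si * fn_g ** (3 - si)
                ll += cnt * np.log(np.maximum(p, 1e-300))
            assert fit.loglik >= ll.max() - 1e-6


class TestPearsonGof:
    def test_zero_when_observed_equals_expected(self):
        counts = table1_fixture()
        fitted = {p: float(c) for p, c in counts.counts.items()}
        chi2, _ = pearson_gof(counts, fitted)
        assert chi2 == 0.0

    def test_hand_arithmetic_two_cells(self):
        counts = PatternCounts(counts={(0,): 60, (1,): 40}, K=1)
        chi2, ncells = pearson_gof(counts, {(0,): 50.0, (1,): 50.0})
        assert chi2 == pytest.approx(4.0)
        assert ncells == 2

    def test_matches_scipy_chisquare(self, rng):
        pats = all_patterns(3)
        obs = rng.integers(1, 100, 8)
        exp = np.full(8, obs.sum() / 8.0)
        counts = PatternCounts(counts=dict(zip(pats, map(int, obs))), K=3)
        chi2, _ = pearson_gof(counts, dict(zip(pats, exp)))
        ref = stats.chisquare(obs, exp).statistic
        assert chi2 == pytest.approx(ref, rel=1e-12)

    def test_total_mismatch_rejected(self):
        counts = PatternCounts(counts={(0,): 60, (1,): 40}, K=1)
        with pytest.raises(ValueError, match="total"):
            pearson_gof(counts, {(0,): 10.0, (1,): 10.0})

    def test_pooling_small_cells(self):
        counts = PatternCounts(counts={(0, 0): 96, (0, 1): 2, (1, 0): 1, (1, 1): 1}, K=2)
        fitted = {(0, 0): 99.6, (0, 1): 0.2, (1, 0): 0.1, (1, 1): 0.1}
        chi2_pooled, used = pearson_gof(counts, fitted, pool_floor=0.5)
        assert used == 2  # three tiny cells pooled into one remainder
        expected = (96 - 99.6) ** 2 / 99.6 + (4 - 0.4) ** 2 / 0.4
        assert chi2_pooled == pytest.approx(expected)


class TestDf:
    @pytest.mark.parametrize("K,model,expected", [(4, "ci", 6), (3, "ci", 0), (4, "re", 5), (5, "re", 19)])
    def test_values(self, K, model, expected):
        assert lcm_df(K, model) == expected

    def test_unidentifiable_raises(self):
        with pytest.raises(ValueError, match="not identifiable"):
            lcm_df(2, "re")


class TestRandomEffects:
    def test_sigma_zero_collapses_to_ci(self, rng):
        K = 3
        a0 = special.ndtri(rng.uniform(0.01, 0.1, K))
        a1 = special.ndtri(rng.uniform(0.7, 0.95, K))
        re = LcmREParams(eta=0.1, a0=a0, a1=a1, sigma=0.0)
        ci = LcmCIParams(eta=0.1, fp=special.ndtr(a0), fn=1 - special.ndtr(a1))
        for pat in all_patterns(K):
            assert re_pattern_prob(re, pat) == pytest.approx(
                ci_pattern_prob(ci, pat), rel=1e-10
            )

    def test_normalization(self, rng):
        params = LcmREParams(
            eta=0.2, a0=rng.normal(-2, 0.5, 4), a1=rng.normal(1, 0.5, 4), sigma=1.2
        )
        total = sum(re_pattern_prob(params, p) for p in all_patterns(4))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_adaptive_quadrature_oracle(self):
        params = LcmREParams(
            eta=0.15, a0=np.array([-2.0, -1.5, -2.5]), a1=np.array([0.8, 1.2, 0.5]), sigma=1.2
        )
        pattern = (1, 0, 1)

        def integrand(b, a):
            p = special.ndtr(a + params.sigma * b)
            lik = np.prod([pk if y else 1 - pk for pk, y in zip(p, pattern)])
            return lik * stats.norm.pdf(b)

        expected = 0.0
        for d, w in ((0, 1 - params.eta), (1, params.eta)):
            a = params.a0 if d == 0 else params.a1
            val, _ = integrate.quad(integrand, -12, 12, args=(a,), epsabs=1e-12)
            expected += w * val
        assert re_pattern_prob(params, pattern, n_quad=60) == pytest.approx(
            expected, abs=1e-6
        )

    def test_n_quad_floor(self):
        params = LcmREParams(eta=0.1, a0=np.zeros(3), a1=np.ones(3), sigma=1.0)
        with pytest.raises(ValueError):
            re_pattern_prob(params, (1, 0, 0), n_quad=5)


class TestMarginalRates:
    def test_sigma_zero(self):
        params = LcmREParams(eta=0.1, a0=np.array([-2.0]), a1=np.array([1.0]), sigma=0.0)
        fp, fn = marginal_rates(params)
        assert fp[0] == pytest.approx(special.ndtr(-2.0))
        assert fn[0] == pytest.approx(1 - special.ndtr(1.0))

    def test_zero_intercept_gives_half(self):
        params = LcmREParams(eta=0.1, a0=np.array([0.0]), a1=np.array([1.0]), sigma=3.0)
        fp, _ = marginal_rates(params)
        assert fp[0] == pytest.approx(0.5)

    def test_matches_numerical_integration(self):
        params = LcmREParams(eta=0.1, a0=np.array([-1.0]), a1=np.array([1.0]), sigma=2.0)

        def marg(a):
            val, _ = integrate.quad(
                lambda b: special.ndtr(a + params.sigma * b) * stats.norm.pdf(b), -12, 12
            )
            return val

        fp, fn = marginal_rates(params)
        assert fp[0] == pytest.approx(marg(-1.0), abs=1e-8)
        assert 1 - fn[0] == pytest.approx(marg(1.0), abs=1e-8)


class TestFitRe:
    def test_nesting_on_table1(self):
        counts = table1_fixture()
        ci = fit_ci(counts, n_restarts=10, seed=0)
        re = fit_re(counts, n_restarts=4, seed=0)
        assert re.loglik >= ci.loglik - 1e-6
        assert re.df == 5

    def test_boundary_recovery_sigma_zero(self, rng):
        true = LcmCIParams(
            eta=0.05, fp=np.array([0.01, 0.02, 0.005, 0.03]), fn=np.array([0.2, 0.3, 0.1, 0.15])
        )
        counts = counts_from_probs(true, 4, 50_000, rng)
        fit = fit_re(counts, n_restarts=4, seed=0)
        fp, fn = marginal_rates(fit.params)
        assert fit.params.sigma < 0.35
        assert np.allclose(fp, true.fp, atol=0.01)
        assert np.allclose(fn, true.fn, atol=0.05)

    def test_k3_rejected(self):
        counts = PatternCounts(counts={p: 1 for p in all_patterns(3)}, K=3)
        with pytest.raises(ValueError, match="K >= 4"):
            fit_re(counts)
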