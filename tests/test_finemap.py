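"""SuSiE fitting against exact single-effect oracles, plus causal-locus
utilities."""

import numpy as np
import pytest
from scipy import stats

from hfs.association import AssocResult
from hfs.finemap import (
    call_causal,
    fisher_enrichment,
    flag_pleiotropic,
    match_controls,
    susie_fit,
    tagged_variance,
)


def single_effect_oracle(X, y, v, sigma2):
    """Exhaustive single-effect Bayesian regression.

    For each column j: conjugate posterior under b ~ N(0, v), noise
    variance sigma2, uniform prior over columns. Returns (alpha, mu1).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    d = (Xc**2).sum(axis=0)
    bhat = Xc.T @ yc / d
    shat2 = sigma2 / d
    log_bf = 0.5 * np.log(shat2 / (shat2 + v)) + 0.5 * (bhat**2 / shat2) * v / (
        v + shat2
    )
    w = log_bf - log_bf.max()
    alpha = np.exp(w) / np.exp(w).sum()
    s1 = 1.0 / (1.0 / v + d / sigma2)
    mu1 = s1 * (Xc.T @ yc) / sigma2
    return alpha, mu1


class TestSusieOracle:
    def test_l1_matches_exact_softmax(self):
        """With L = 1 and fixed variances, IBSS is the closed-form
        single-effect posterior."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            X = rng.standard_normal((200, 50))
            beta = np.zeros(50)
            beta[rng.integers(50)] = 0.4
            y = X @ beta + rng.standard_normal(200)
            v, s2 = 0.2, 1.0
            fit = susie_fit(
                X, y, L=1, prior_variance=v, residual_variance=s2,
                estimate_prior_variance=False, estimate_residual_variance=False,
            )
            alpha, mu1 = single_effect_oracle(X, y, v, s2)
            assert np.abs(fit.alpha[0] - alpha).max() < 1e-6
            assert np.abs(fit.mu[0] - mu1).max() < 1e-6
            assert np.abs(fit.pip - alpha).max() < 1e-6

    def test_overwhelming_signal_pip(self):
        """Strong single signal in near-orthogonal design: PIP ~ 1 and it
        agrees with the exact single-effect computation."""
        rng = np.random.default_rng(11)
        n = 2000
        X = rng.standard_normal((n, 20))
        y = 0.45 * X[:, 4] + rng.standard_normal(n)  # per-column NCP ~ 400
        fit = susie_fit(X, y, L=10)
        assert fit.pip[4] > 0.99
        alpha, _ = single_effect_oracle(X, y, fit.prior_variances[0], fit.sigma2)
        assert alpha[4] > 0.99

    def test_null_reports_no_credible_set(self):
        """On pure noise, credible sets are (almost) never reported."""
        rng = np.random.default_rng(12)
        n_with_cs = 0
        for _ in range(10):
            X = rng.standard_normal((300, 40))
            y = rng.standard_normal(300)
            fit = susie_fit(X, y, L=10)
            n_with_cs += bool(fit.credible_sets)
        assert n_with_cs <= 1

    def test_alpha_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((100, 30))
        y = X[:, 3] * 0.5 + rng.standard_normal(100)
        fit = susie_fit(X, y, L=5)
        assert np.allclose(fit.alpha.sum(axis=1), 1.0)
        assert ((fit.pip >= 0) & (fit.pip <= 1)).all()

    def test_credible_set_coverage_attained(self):
        rng = np.random.default_rng(14)
        n = 500
        z = rng.standard_normal(n)
        # a correlated pair sharing the signal: the set should cover both
        X = np.column_stack([z + 0.1 * rng.standard_normal(n),
                             z + 0.1 * rng.standard_normal(n),
                             rng.standard_normal((n, 8)).T.reshape(8, n).T])
        y = z * 0.4 + rng.standard_normal(n)
        fit = susie_fit(X, y, L=5, coverage=0.95)
        assert fit.credible_sets
        cs = fit.credible_sets[0]
        assert cs.coverage >= 0.95
        assert set(cs.members) >= {0, 1} or fit.pip[[0, 1]].max() > 0.4

    def test_constant_columns_removed_and_reported(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((100, 5))
        X[:, 2] = 7.0
        y = X[:, 0] * 0.8 + rng.standard_normal(100)
        fit = susie_fit(X, y, L=2)
        assert not fit.kept[2] and fit.pip[2] == 0.0

    def test_l_sweep_stability(self):
        """The set of confidently causal loci is stable for L in 2..10."""
        rng = np.random.default_rng(16)
        n = 1500
        X = rng.standard_normal((n, 60))
        y = 0.3 * X[:, 10] - 0.25 * X[:, 40] + rng.standard_normal(n)
        calls = []
        for L in (2, 5, 10):
            fit = susie_fit(X, y, L=L)
            calls.append(frozenset(np.nonzero(fit.pip > 0.95)[0]))
        assert calls[0] == calls[1] == calls[2] == frozenset({10, 40})

    def test_input_validation(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError, match="10 individuals"):
            susie_fit(rng.standard_normal((5, 3)), rng.standard_normal(5))
        with pytest.raises(ValueError, match="non-constant"):
            susie_fit(np.ones((20, 3)), rng.standard_normal(20))


class TestCallCausal:
    def test_strict_threshold(self):
        pips = {"A": 0.96, "B": 0.95, "C": 0.2}
        assert call_causal(pips) == {"A"}

    def test_pleiotropic_flag(self):
        by_trait = {"t1": {"A", "B"}, "t2": {"A"}, "t3": set()}
        assert flag_pleiotropic(by_trait) == {"A"}


def res(lid, pos, p, chrom="chr1"):
    return AssocResult(lid, 0.1, 0.02, p, 50, chrom=chrom,
                       start=pos - 2048, end=pos + 2048)


class TestMatchControls:
    def test_nearest_matching_candidate_wins(self):
        causal = [res("C1", 1_000_000, 1e-12)]
        cands = [res("N1", 1_010_000, 2e-12), res("N2", 1_100_000, 1e-12)]
        out = match_controls(causal, cands)
        assert out["C1"] == ("N1", False)

    def test_fallback_when_no_p_match(self):
        causal = [res("C1", 1_000_000, 1e-12)]
        cands = [res("N1", 1_010_000, 1e-4)]
        out = match_controls(causal, cands)
        assert out["C1"] == ("N1", True)

    def test_greedy_competition(self):
        """Two causal loci wanting the same control: smaller p wins it."""
        causal = [res("C1", 1_000_000, 1e-12), res("C2", 1_020_000, 1e-11)]
        cands = [res("N1", 1_005_000, 1e-12), res("N2", 2_000_000, 1e-11)]
        out = match_controls(causal, cands)
        assert out["C1"] == ("N1", False)
        assert out["C2"] == ("N2", False)


class TestFisherEnrichment:
    def test_cross_product_odds_ratio(self):
        or_, p, flagged = fisher_enrichment(10, 10, 5, 15)
        assert or_ == pytest.approx(3.0)
        assert not flagged

    def test_identical_rates_null(self):
        or_, p, _ = fisher_enrichment(5, 15, 5, 15)
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_two_sided_p_hypergeometric_oracle(self):
        """[[8,2],[2,8]]: enumerate the hypergeometric tail directly."""
        or_, p, _ = fisher_enrichment(8, 2, 2, 8)
        pmf = [stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = pmf[8]
        expected = sum(q for q in pmf if q <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-6)
        assert p == pytest.approx(0.023, abs=0.0005)

    def test_zero_cell_haldane(self):
        or_, p, flagged = fisher_enrichment(10, 0, 5, 15)
        assert flagged and np.isfinite(or_) and or_ > 1

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 0, 0)


class TestTaggedVariance:
    def test_exact_linear_r2_one(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        r2, aic, flagged = tagged_variance(X, y)
        assert r2 == pytest.approx(1.0)
        assert not flagged

    def test_null_r2_near_p_over_n(self):
        """Under the null, E[R^2] ~ p/n for OLS."""
        rng = np.random.default_rng(18)
        vals = []
        n, p = 200, 10
        for _ in range(200):
            r2, _, _ = tagged_variance(rng.standard_normal((n, p)),
                                       rng.standard_normal(n))
            vals.append(r2)
        assert np.mean(vals) == pytest.approx(p / n, abs=0.015)

    def test_monotone_in_columns(self, rng):
        X = rng.standard_normal((100, 4))
        y = X[:, 0] + rng.standard_normal(100)
        r2_small, _, _ = tagged_variance(X[:, :2], y)
        r2_big, _, _ = tagged_variance(X, y)
        assert r2_big >= r2_small - 1e-12

    def test_rank_deficient_flagged(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x])
        y = x + rng.standard_normal(50)
        r2, _, flagged = tagged_variance(X, y)
        assert flagged and 0 <= r2 <= 1
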