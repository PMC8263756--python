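import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

from loyburden.association import (GeneSetAssociation, NullTraitModel, acat, acat_v,
                                   burden_test, cauchy_omnibus, exome_scan, fit_null,
                                   per_variant_score_pvalues, skat_test)
from loyburden.burden import BurdenSet, carrier_indicator
from loyburden.quadform import mixture_chisq_tail
from loyburden.synthetic import simulate_null_gene, simulate_planted_gene


def irls_logistic_oracle(y, X, maxiter=200, tol=1e-12):
    """Hand-rolled Newton–Raphson logistic fit, independent of statsmodels."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestNullModel:
    def test_exact_linear_fit_zero_residuals(self, rng):
        X = rng.standard_normal((100, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = 2.0 + X @ beta
        res = fit_null(y, X, "gaussian")
        assert np.allclose(res.resid, 0, atol=1e-10)
        # residuals orthogonal to design columns
        assert np.allclose(res.exog.T @ res.resid, 0, atol=1e-8)

    def test_intercept_only_binomial_matches_prevalence(self, rng):
        y = np.r_[np.ones(25), np.zeros(75)]
        res = fit_null(y, np.empty((100, 0)), "binomial")
        assert np.allclose(res.fitted, 0.25, atol=1e-8)

    def test_binomial_matches_independent_irls(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = (rng.random(n) < expit(X @ np.array([-0.5, 0.8, -0.3, 0.1]))).astype(float)
        res = fit_null(y, X[:, 1:], "binomial")
        oracle = irls_logistic_oracle(y, X)
        assert np.allclose(res.params, oracle, atol=1e-8)

    def test_gaussian_matches_lstsq_oracle(self, rng):
        n = 300
        X = rng.standard_normal((n, 4))
        y = X @ rng.standard_normal(4) + rng.standard_normal(n)
        res = fit_null(y, X, "gaussian")
        oracle = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        assert np.allclose(res.params, oracle, atol=1e-10)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            fit_null([0, 1, 2], np.ones((2, 1)), "gaussian")
        with pytest.raises(ValueError):
            fit_null([0, 2], np.ones((2, 1)), "binomial")
        with pytest.raises(ValueError):
            NullTraitModel([0, 1], np.ones((2, 1)), family="poisson")


class TestBurdenTest:
    def test_single_variant_set_equals_score_test(self, rng):
        n = 400
        X = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        null = fit_null(y, X, "gaussian")
        g = (rng.random(n) < 0.03).astype(float)
        res = burden_test(g, null)
        _, _, p_score = null.score_test(g)
        assert res.p_score == pytest.approx(p_score, rel=1e-12)

    def test_balanced_table_gives_null_or(self):
        y = np.r_[np.ones(50), np.zeros(50), np.ones(50), np.zeros(50)]
        c = np.r_[np.zeros(100), np.ones(100)]
        null = fit_null(y, np.empty((200, 0)), "binomial")
        res = burden_test(c, null)
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_zero_carriers_flagged_undefined(self, rng):
        y = rng.standard_normal(100)
        null = fit_null(y, np.empty((100, 0)), "gaussian")
        res = burden_test(np.zeros(100), null)
        assert not res.defined
        assert "degenerate_carrier" in res.flags

    def test_missing_carriers_dropped_complete_case(self, rng):
        n = 300
        y = rng.standard_normal(n)
        null = fit_null(y, np.empty((n, 0)), "gaussian")
        c = (rng.random(n) < 0.05).astype(float)
        c[:10] = np.nan
        res = burden_test(c, null)
        assert res.n_obs == n - 10
        assert "carrier_missingness_refit" in res.flags

    def test_separation_uses_firth_fallback(self):
        # carriers are all cases: infinite MLE, finite penalised estimate
        y = np.r_[np.ones(5), np.zeros(95)].astype(float)
        c = np.r_[np.ones(5), np.zeros(95)].astype(float)
        null = fit_null(y, np.empty((100, 0)), "binomial")
        res = burden_test(c, null)
        assert "firth_fallback" in res.flags
        assert np.isfinite(res.beta) and np.isfinite(res.se)

    def test_gaussian_effect_recovery(self, rng):
        betas = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            G, carrier, y = simulate_planted_gene(r, 8000, 0.93)
            null = fit_null(y, np.empty((8000, 0)), "gaussian")
            betas.append(burden_test(carrier.astype(float), null).beta)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(0.93, abs=4 * se)


class TestAcat:
    def test_identities(self):
        assert acat_v([0.05]) == pytest.approx(0.05, abs=1e-12)
        assert acat_v([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
        assert cauchy_omnibus(0.3, 0.3, 0.3) == pytest.approx(0.3, abs=1e-12)
        assert cauchy_omnibus(0.123, np.nan, np.nan) == pytest.approx(0.123, abs=1e-12)

    def test_matches_longdouble_oracle(self, rng):
        for _ in range(100):
            m = rng.integers(1, 12)
            p = rng.uniform(1e-8, 1 - 1e-8, m)
            w = rng.uniform(0.1, 5.0, m)
            pl = np.longdouble(p)
            wl = np.longdouble(w)
            T = np.sum(wl * np.tan((np.longdouble(0.5) - pl) * np.longdouble(np.pi))) / wl.sum()
            expected = float(np.longdouble(0.5) - np.arctan(T) / np.longdouble(np.pi))
            assert acat_v(p, w) == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0.01, 0.99, 6)
        assert acat_v(p) == pytest.approx(acat_v(p[::-1]), abs=1e-15)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=8),
           st.integers(0, 7), st.floats(0.1, 0.9))
    def test_monotone_in_each_component(self, ps, idx, shrink):
        idx = idx % len(ps)
        smaller = list(ps)
        if smaller[idx] * shrink == smaller[idx]:
            return
        smaller[idx] = smaller[idx] * shrink
        assert acat_v(smaller) < acat_v(ps)

    def test_tiny_p_tail_substitution(self):
        p = acat_v([1e-20, 0.5])
        assert 0 < p < 1e-18

    def test_zero_p_clipped_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="loyburden.association"):
            p = acat_v([0.0, 0.5])
        assert p > 0
        assert "clipped" in caplog.text

    def test_input_validation(self):
        with pytest.raises(ValueError):
            acat([])
        with pytest.raises(ValueError):
            acat([0.5, np.nan])
        with pytest.raises(ValueError):
            acat([0.5], weights=[0.0])
        assert np.isnan(cauchy_omnibus(np.nan, np.nan))


class TestMixtureChisqTail:
    def test_single_eigenvalue_matches_chi2_1(self):
        for q in [1e-3, 0.5, 1.0, 3.84, 10.0, 40.0]:
            assert mixture_chisq_tail([1.0], q) == pytest.approx(
                stats.chi2.sf(q, 1), abs=1e-10)

    def test_equal_eigenvalues_match_chi2_3(self):
        for q in [0.1, 1.0, 7.81, 25.0]:
            assert mixture_chisq_tail([1, 1, 1], q) == pytest.approx(
                stats.chi2.sf(q, 3), abs=1e-8)

    def test_scaling_invariance(self):
        assert mixture_chisq_tail([2.0], 7.68) == pytest.approx(
            stats.chi2.sf(3.84, 1), abs=1e-10)

    def test_matches_monte_carlo(self, rng):
        lam = rng.uniform(0.2, 2.5, 5)
        draws = (lam * rng.chisquare(1, size=(200_000, 5))).sum(axis=1)
        for q_level in [0.5, 0.9, 0.99]:
            q = np.quantile(draws, q_level)
            p_mc = (draws > q).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / 200_000)
            assert abs(mixture_chisq_tail(lam, q) - p_mc) < 3 * se

    def test_validation(self):
        with pytest.raises(ValueError):
            mixture_chisq_tail([-1.0], 1.0)
        with pytest.raises(ValueError):
            mixture_chisq_tail([0.0], 1.0)
        with pytest.raises(ValueError):
            mixture_chisq_tail([1.0], -1.0)
        assert mixture_chisq_tail([1.0], 0.0) == 1.0


class TestSkat:
    def test_duplicated_column_equals_sqrt2_weight(self, rng):
        n = 300
        y = rng.standard_normal(n)
        null = fit_null(y, np.empty((n, 0)), "gaussian")
        g = (rng.random(n) < 0.05).astype(float)
        single = skat_test(g[:, None], null, weights=[np.sqrt(2.0)])
        doubled = skat_test(np.column_stack([g, g]), null)
        assert doubled.Q == pytest.approx(single.Q, rel=1e-12)
        assert doubled.p == pytest.approx(single.p, rel=1e-6)

    def test_all_zero_weights_degenerate(self, rng):
        n = 200
        null = fit_null(rng.standard_normal(n), np.empty((n, 0)), "gaussian")
        G = (rng.random((n, 3)) < 0.05).astype(float)
        res = skat_test(G, null, weights=np.zeros(3))
        assert res.Q == 0.0 and res.p == 1.0 and "all_zero_weights" in res.flags

    def test_zero_variance_columns_dropped(self, rng):
        n = 200
        null = fit_null(rng.standard_normal(n), np.empty((n, 0)), "gaussian")
        G = np.column_stack([(rng.random(n) < 0.05).astype(float), np.zeros(n)])
        res = skat_test(G, null)
        assert res.n_variants_used == 1
        assert "dropped_zero_variance" in res.flags

    def test_analytic_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(77)
        n = 200
        X = rng.standard_normal((n, 2))
        y = rng.standard_normal(n) + 0.2 * X[:, 0]
        null = fit_null(y, X, "gaussian")
        G = (rng.random((n, 5)) < 0.06).astype(float)
        res = skat_test(G, null)
        n_perm = 1000
        count = 0
        for _ in range(n_perm):
            r = rng.permutation(null.resid)
            q = float(np.sum((G.T @ r) ** 2))
            count += q >= res.Q
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < 3 * se + 1e-3


class TestNullUniformity:
    def test_gaussian_null_pvalues_uniform(self):
        rng = np.random.default_rng(123)
        n, n_genes = 1500, 250
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n) + X @ np.array([0.3, -0.2, 0.1])
        null = fit_null(y, X, "gaussian")
        pb, ps, pa, po = [], [], [], []
        for _ in range(n_genes):
            G = simulate_null_gene(rng, n, 8, maf_low=0.002, maf_high=0.005)
            c = carrier_indicator(pd.DataFrame(G.astype(float)))
            res = burden_test(c.to_numpy(), null)
            sk = skat_test(G, null)
            vp = per_variant_score_pvalues(G.astype(float), null)
            pa.append(acat_v(vp[~np.isnan(vp)]))
            pb.append(res.p_wald)
            ps.append(sk.p)
            po.append(cauchy_omnibus(res.p_wald, sk.p, pa[-1]))
        for name, ps_ in [("burden", pb), ("skat", ps), ("acatv", pa), ("omni", po)]:
            ks = stats.kstest(ps_, "uniform").pvalue
            frac = np.mean(np.asarray(ps_) < 0.05)
            lo, hi = stats.binom.interval(0.99, n_genes, 0.05)
            assert ks > 0.01, (name, ks)
            assert lo / n_genes <= frac <= hi / n_genes, (name, frac)


class TestExomeScan:
    def _sets(self, rng, n, n_genes, planted_gene=None, y=None):
        sets = []
        for gi in range(n_genes):
            gene = f"GENE{gi:03d}"
            if planted_gene == gene:
                G, carrier, _ = simulate_planted_gene(rng, n, 0.0)
            else:
                G = simulate_null_gene(rng, n, 6)
            keys = [f"chr1:{gi * 100 + j}:A:T" for j in range(G.shape[1])]
            dos = pd.DataFrame(G.astype(float), columns=keys)
            sets.append(BurdenSet(gene=gene, model="loss_of_function",
                                  variant_keys=keys,
                                  mafs=np.full(G.shape[1], 1e-3),
                                  macs=G.sum(axis=0).astype(int),
                                  cadd=np.full(G.shape[1], 25.0), dosages=dos,
                                  carrier=carrier_indicator(dos)))
        return sets

    def test_significance_flag_strict_inequality(self):
        df = pd.DataFrame([{"p_omnibus": 1.6e-6}, {"p_omnibus": 1.59e-6}])
        from loyburden.association import EXOME_WIDE_ALPHA
        flags = df["p_omnibus"] < EXOME_WIDE_ALPHA
        assert flags.tolist() == [False, True]

    def test_null_scan_produces_no_exome_wide_hits(self, rng):
        n = 800
        y = rng.standard_normal(n)
        null = fit_null(y, np.empty((n, 0)), "gaussian")
        sets = self._sets(rng, n, 60)
        out = exome_scan(sets, null)
        assert out["significant"].sum() == 0
        assert list(out.columns)[:2] == ["gene", "model"]

    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 4000
        G, carrier, y = simulate_planted_gene(rng, n, 0.93)
        null = fit_null(y, np.empty((n, 0)), "gaussian")
        sets = self._sets(rng, n, 30)
        keys = [f"chr1:P{j}:A:T" for j in range(G.shape[1])]
        dos = pd.DataFrame(G.astype(float), columns=keys)
        sets.append(BurdenSet(gene="PLANTED", model="loss_of_function",
                              variant_keys=keys, mafs=np.full(27, 1e-3),
                              macs=G.sum(axis=0).astype(int),
                              cadd=np.full(27, 30.0), dosages=dos,
                              carrier=carrier_indicator(dos)))
        out = exome_scan(sets, null)
        assert out.iloc[0]["gene"] == "PLANTED"

    def test_cadd_weighting_runs(self, rng):
        n = 500
        null = fit_null(rng.standard_normal(n), np.empty((n, 0)), "gaussian")
        sets = self._sets(rng, n, 3)
        out = exome_scan(sets, null, weights="cadd")
        assert len(out) == 3


def test_gene_set_results_summary(rng):
    n = 1000
    G, carrier, y = simulate_planted_gene(rng, n, 0.9)
    null = fit_null(y, np.empty((n, 0)), "gaussian")
    keys = [f"chr1:{j}:A:T" for j in range(27)]
    dos = pd.DataFrame(G.astype(float), columns=keys)
    s = BurdenSet(gene="G", model="loss_of_function", variant_keys=keys,
                  mafs=np.full(27, 1e-3), macs=G.sum(axis=0).astype(int),
                  cadd=np.full(27, 30.0), dosages=dos,
                  carrier=carrier_indicator(dos))
    res = GeneSetAssociation(s, null).fit()
    text = res.summary()
    assert "burden" in text and "SKAT" in text and "omnibus" in text
    assert res.n_carriers == 40
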