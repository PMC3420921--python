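import numpy as np
import pytest
from scipy import stats

from ccagwas import (
    Effect,
    SimulationConfig,
    canonical_loadings,
    canonical_r2,
    conditional_multivariate_test,
    min_univariate_p,
    multivariate_test,
    simulate_dataset,
    univariate_test,
    wilks_to_F,
)
from ccagwas.assoc import UnivariateResult
from .oracles import ols_r2, ols_residuals


def _dosage(rng, n, p=0.3):
    return rng.binomial(2, p, n).astype(float)


class TestUnivariateTest:
    def test_orthogonal_metabolite_gives_null(self, rng):
        g = _dosage(rng, 500)
        y = ols_residuals(rng.standard_normal(500), g)  # orthogonal by construction
        res = univariate_test(g, y)
        assert abs(res.beta) < 1e-10
        assert res.p > 0.999

    def test_recovers_planted_slope(self, rng):
        g = _dosage(rng, 1000)
        y = 0.5 * g + 0.1 * rng.standard_normal(1000)
        res = univariate_test(g, y)
        assert 0.48 <= res.beta <= 0.52

    def test_allele_recoding_negates_beta(self, rng):
        g = _dosage(rng, 300)
        y = 0.2 * g + rng.standard_normal(300)
        a = univariate_test(g, y)
        b = univariate_test(2.0 - g, y)
        assert b.beta == pytest.approx(-a.beta, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)

    def test_monomorphic_flagged(self, rng):
        res = univariate_test(np.zeros(50), rng.standard_normal(50))
        assert res.flag == "monomorphic"
        assert np.isnan(res.p)

    def test_complete_case_n(self, rng):
        g = _dosage(rng, 100)
        g[:10] = np.nan
        res = univariate_test(g, rng.standard_normal(100))
        assert res.n == 90


class TestCanonicalR2:
    def test_residualized_genotype_gives_zero(self, rng):
        Y = rng.standard_normal((300, 4))
        g = _dosage(rng, 300)
        g_res = ols_residuals(g, Y)
        assert canonical_r2(g_res, Y) < 1e-10

    def test_exact_linear_combination_degenerate(self, rng):
        Y = rng.standard_normal((100, 3))
        g = Y @ np.array([0.5, -1.0, 2.0]) + 1.0
        assert canonical_r2(g, Y) >= 1.0 - 1e-10

    def test_matches_least_squares_oracle(self, rng):
        Y = rng.standard_normal((200, 5))
        g = _dosage(rng, 200)
        assert canonical_r2(g, Y) == pytest.approx(ols_r2(g, Y), abs=1e-10)

    def test_affine_invariance(self, rng):
        """rho^2 is unchanged by any invertible affine map of the metabolites."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            Y = r.standard_normal((150, 4))
            g = r.binomial(2, 0.3, 150).astype(float)
            A = r.standard_normal((4, 4)) + 4 * np.eye(4)
            b = r.standard_normal(4)
            assert canonical_r2(g, Y @ A + b) == pytest.approx(
                canonical_r2(g, Y), abs=1e-8
            )

    def test_rank_deficient_y_rejected(self, rng):
        Y = rng.standard_normal((100, 2))
        Y = np.column_stack([Y, Y[:, 0] * 2.0])
        with pytest.raises(ValueError, match="rank deficient"):
            canonical_r2(_dosage(rng, 100), Y)

    def test_constant_genotype_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            canonical_r2(np.ones(50), rng.standard_normal((50, 2)))


class TestWilksToF:
    def test_null_rho2(self):
        lam, F, df1, df2, p = wilks_to_F(0.0, 100, 3)
        assert (lam, F, p) == (1.0, 0.0, 1.0)

    def test_stated_arithmetic(self):
        lam, F, df1, df2, p = wilks_to_F(0.5, 103, 2)
        assert lam == 0.5
        assert F == pytest.approx(50.0)
        assert (df1, df2) == (2, 100)

    def test_k1_equals_t_squared(self, rng):
        g = _dosage(rng, 200)
        y = 0.1 * g + rng.standard_normal(200)
        uni = univariate_test(g, y)
        rho2 = canonical_r2(g, y[:, None])
        lam, F, df1, df2, p = wilks_to_F(rho2, 200, 1)
        assert F == pytest.approx(uni.t**2, rel=1e-10)
        assert p == pytest.approx(uni.p, rel=1e-8, abs=1e-12)

    def test_lambda_identity(self, rng):
        for rho2 in (0.0, 0.1, 0.63, 0.999):
            lam, *_ = wilks_to_F(rho2, 50, 4)
            assert lam == 1.0 - rho2

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            wilks_to_F(0.2, 5, 4)


class TestCanonicalLoadings:
    def test_k1_loading_is_unit(self, rng):
        g = _dosage(rng, 200)
        y = 0.3 * g + rng.standard_normal(200)
        loadings, _, flag = canonical_loadings(y[:, None], g)
        assert flag is None
        assert abs(loadings[0]) == pytest.approx(1.0, abs=1e-12)

    def test_single_affected_metabolite_dominates(self):
        r = np.random.default_rng(42)
        n = 5000
        g = r.binomial(2, 0.3, n).astype(float)
        var_g = g.var()
        beta = np.sqrt(0.01 / var_g)
        Y = np.column_stack([
            beta * g + np.sqrt(0.99) * r.standard_normal(n),
            r.standard_normal(n),
        ])
        loadings, _, _ = canonical_loadings(Y, g)
        assert abs(loadings[0]) > 0.9
        assert abs(loadings[1]) < 0.1

    def test_bounded_by_one(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            Y = r.standard_normal((60, 3))
            g = r.binomial(2, 0.25, 60).astype(float)
            loadings, _, flag = canonical_loadings(Y, g)
            if flag is None:
                assert np.all(np.abs(loadings) <= 1.0)

    def test_orientation_positive_with_dosage(self, rng):
        g = _dosage(rng, 1000)
        Y = np.column_stack([0.5 * g + rng.standard_normal(1000)])
        loadings, coef, _ = canonical_loadings(Y, g)
        # variate oriented toward minor-allele count: positive effect -> positive loading
        assert loadings[0] > 0


class TestMultivariateTest:
    def test_singleton_network_matches_univariate(self, rng):
        g = _dosage(rng, 400)
        y = 0.1 * g + rng.standard_normal(400)
        uni = univariate_test(g, y)
        mv = multivariate_test(g, y[:, None], ["m"])
        assert mv.p == pytest.approx(uni.p, rel=1e-8, abs=1e-12)
        assert mv.wilks_lambda == 1.0 - mv.rho2

    def test_permutation_null_uniform(self):
        """Under permutation of the genotype, p-values are uniform."""
        r = np.random.default_rng(7)
        n = 300
        Y = r.standard_normal((n, 4))
        g = r.binomial(2, 0.3, n).astype(float)
        ps = []
        for _ in range(1000):
            ps.append(multivariate_test(r.permutation(g), Y, list("abcd")).p)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05

    def test_null_calibration_many_snps(self):
        """Type-I error at alpha=0.05 across 2000 null SNPs, k=8, n=2000."""
        r = np.random.default_rng(99)
        n = 2000
        Y = r.standard_normal((n, 8))
        mets = [f"m{j}" for j in range(8)]
        hits = 0
        n_snps = 2000
        G = r.binomial(2, r.uniform(0.05, 0.5, n_snps), (n, n_snps)).astype(float)
        for j in range(n_snps):
            if multivariate_test(G[:, j], Y, mets).p < 0.05:
                hits += 1
        assert 0.040 <= hits / n_snps <= 0.060

    def test_degenerate_flagged_not_raised(self, rng):
        Y = rng.standard_normal((100, 2))
        g = Y @ np.array([1.0, 2.0])
        res = multivariate_test(g, Y, ["a", "b"])
        assert res.flag == "degenerate"
        assert res.p == 0.0

    def test_missing_dosages_complete_case(self, rng):
        g = _dosage(rng, 500)
        g[:50] = np.nan
        Y = rng.standard_normal((500, 3))
        res = multivariate_test(g, Y, list("abc"))
        assert res.n == 450


def _planted_scenario(seed, n=5000, k=6, hit_members=4, var_frac=0.01, within=0.6):
    pattern = [1.0] * hit_members + [0.0] * (k - hit_members)
    cfg = SimulationConfig(
        n_samples_per_cohort=(n // 2, n - n // 2),
        n_snps=3,
        network_spec=[(k, within, 0.0)],
        effect_spec=[Effect(0, 0, var_frac, pattern=pattern)],
        covariate_spec={},
        missing_rate_genotype=0.0,
        seed=seed,
    )
    return simulate_dataset(cfg)


class TestConditionalTest:
    def test_conditioning_on_target_kills_signal(self):
        geno, pheno, truth = _planted_scenario(1)
        g = geno.dosages[:, 0]
        Y = pheno.metabolite_matrix()
        res = conditional_multivariate_test(g, Y, g[:, None], pheno.metabolites)
        assert res.rho2 < 1e-10
        assert res.p > 0.999

    def test_conditioning_on_perfect_proxy_kills_signal(self):
        geno, pheno, truth = _planted_scenario(2)
        g = geno.dosages[:, 0]
        Y = pheno.metabolite_matrix()
        with pytest.warns(UserWarning, match="collinear"):
            # proxy = exact copy; the duplicated column is also reduced
            res = conditional_multivariate_test(
                g, Y, np.column_stack([g, g]), pheno.metabolites
            )
        assert res.rho2 < 1e-10

    def test_conditioning_on_independent_snp_preserves_signal(self):
        geno, pheno, truth = _planted_scenario(3)
        g = geno.dosages[:, 0]
        null_snp = geno.dosages[:, 2]
        Y = pheno.metabolite_matrix()
        base = multivariate_test(g, Y, pheno.metabolites)
        cond = conditional_multivariate_test(g, Y, null_snp[:, None], pheno.metabolites)
        assert abs(np.log10(cond.p) - np.log10(base.p)) < 1.0

    def test_identical_target_warns(self):
        geno, pheno, _ = _planted_scenario(4, n=500)
        g = geno.dosages[:, 0]
        Y = pheno.metabolite_matrix()
        with pytest.warns(UserWarning, match="identical"):
            conditional_multivariate_test(g, Y, g[:, None], pheno.metabolites)

    def test_empty_conditioning_rejected(self, rng):
        g = _dosage(rng, 100)
        Y = rng.standard_normal((100, 2))
        with pytest.raises(ValueError, match="empty"):
            conditional_multivariate_test(g, Y, np.empty((100, 0)), ["a", "b"])


class TestMinUnivariateP:
    def _results(self, ps, mets):
        return [
            UnivariateResult("s", m, 0.1, 0.1, 1.0, p, 100) for p, m in zip(ps, mets)
        ]

    def test_minimum_selected(self):
        res = self._results([0.3, 0.001, 0.2], ["a", "b", "c"])
        p, met = min_univariate_p(res, ["a", "b", "c"])
        assert (p, met) == (0.001, "b")

    def test_singleton_network(self):
        res = self._results([0.42], ["a"])
        assert min_univariate_p(res, ["a"]) == (0.42, "a")

    def test_tie_lexicographic(self):
        res = self._results([0.01, 0.01], ["z", "d"])
        assert min_univariate_p(res, ["z", "d"])[1] == "d"

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            mets = [f"m{j}" for j in range(8)]
            ps = rng.uniform(size=8)
            res = self._results(ps, mets)
            members = list(rng.choice(mets, size=5, replace=False))
            p, _ = min_univariate_p(res, members)
            brute = min(r.p for r in res if r.metabolite_id in members)
            assert p == brute

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            min_univariate_p([], [])
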