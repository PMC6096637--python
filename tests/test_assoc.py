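import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

import recessmap as rm
from recessmap.assoc import (bonferroni_threshold, compute_grm, compute_pcs,
                             encode_genotype, genomic_inflation,
                             genotype_stratified_frequency, logistic_assoc)


class TestEncoding:
    @pytest.mark.parametrize("dosage,model,expected", [
        (2, "recessive", 1.0),
        (1, "recessive", 0.0),
        (0, "recessive", 0.0),
        (1, "additive", 1.0),
        (2, "additive", 2.0),
    ])
    def test_codings(self, dosage, model, expected):
        assert encode_genotype(dosage, model) == expected

    def test_missing_propagates(self):
        out = encode_genotype(np.array([0.0, np.nan, 2.0]), "recessive")
        assert np.isnan(out[1]) and out[2] == 1.0

    def test_invalid_dosage(self):
        with pytest.raises(ValueError):
            encode_genotype(3, "recessive")

    def test_recessive_invariant_to_het_relabelling(self):
        # recessive coding depends only on homozygosity for the effect allele
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 200).astype(float)
        swapped = np.where(g == 1.0, 1.0, g)  # identity on hets by definition
        np.testing.assert_array_equal(encode_genotype(g, "recessive"),
                                      encode_genotype(swapped, "recessive"))
        g01 = np.where(g == 1.0, 0.0, g)
        np.testing.assert_array_equal(encode_genotype(g, "recessive"),
                                      encode_genotype(g01, "recessive"))


class TestGRM:
    def test_identical_individuals(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.5, size=(10, 400)).astype(float)
        G[1] = G[0]  # duplicate individual
        K = compute_grm(G).matrix
        assert K[0, 0] == pytest.approx(K[0, 1])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_unrelated_off_diagonal_near_zero(self):
        rng = np.random.default_rng(1)
        n = 200
        G = rng.binomial(2, rng.uniform(0.1, 0.9, 5000), size=(n, 5000)).astype(float)
        K = compute_grm(G).matrix
        off = K[np.triu_indices(n, 1)]
        # centering forces sum(K) = 0, so the exact off-diagonal mean is
        # -trace / (n(n-1)); individually the entries hover near zero
        assert off.mean() == pytest.approx(-np.trace(K) / (n * (n - 1)), abs=1e-12)
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 6 * off.std()

    def test_symmetric_psd(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.4, size=(50, 300)).astype(float)
        K = compute_grm(G).matrix
        assert np.allclose(K, K.T, atol=1e-10)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_standardized_diagonal_scale(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, rng.uniform(0.05, 0.95, 2000), size=(100, 2000)).astype(float)
        K = compute_grm(G, scale="standardized").matrix
        assert 0.5 <= np.diag(K).mean() <= 2.0

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(np.zeros((10, 5)))


class TestPCA:
    def test_two_populations_separate_on_pc1(self, two_group_cohort):
        G, _, _ = two_group_cohort
        pcs = compute_pcs(G, 2)
        m1, m2 = pcs[:200, 0].mean(), pcs[200:, 0].mean()
        assert m1 * m2 < 0
        # bimodal: within-group spread much smaller than separation
        assert abs(m1 - m2) > 4 * max(pcs[:200, 0].std(), pcs[200:, 0].std())

    def test_orthogonality_and_k0(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.3, size=(60, 200)).astype(float)
        pcs = compute_pcs(G, 3)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8
        assert compute_pcs(G, 0).shape == (60, 0)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            compute_pcs(np.zeros((5, 10)), 5)


class TestLogistic:
    def test_two_by_two_odds_ratio(self):
        x = np.r_[np.ones(50), np.zeros(700)]
        y = np.r_[np.ones(20), np.zeros(30), np.ones(100), np.zeros(600)]
        res = logistic_assoc(y, x, model="recessive")
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-6)
        assert res.n_used == 750 and res.n_homozygous == 50
        assert 0 < res.p_value <= 1

    def test_constant_genotype_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        res = logistic_assoc(y, np.zeros(20))
        assert not res.estimable

    def test_matches_generic_optimizer(self):
        # ML fit against direct likelihood maximisation by scipy
        rng = np.random.default_rng(5)
        n = 180
        x = rng.binomial(2, 0.4, n).astype(float)
        c = rng.normal(size=n)
        eta = -1.0 + 0.6 * x + 0.3 * c
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_assoc(y, x, covars=c)
        X = np.column_stack([np.ones(n), x, c])

        def negll(b):
            e = X @ b
            return np.sum(np.log1p(np.exp(e))) - y @ e

        ref = optimize.minimize(negll, np.zeros(3), method="BFGS").x
        assert res.beta == pytest.approx(ref[1], rel=1e-4)

    def test_symmetric_orthogonal_covariate_leaves_beta_unchanged(self):
        # a +1/-1 covariate balanced within every (x, y) cell has ML
        # coefficient 0, so the genotype beta is unchanged on refit
        blocks = [(0.0, 0.0, 200), (0.0, 1.0, 60), (1.0, 0.0, 100), (1.0, 1.0, 80)]
        xs, ys, zs = [], [], []
        for xv, yv, cnt in blocks:
            xs += [xv] * cnt
            ys += [yv] * cnt
            zs += [1.0, -1.0] * (cnt // 2)
        x, y, z = map(np.asarray, (xs, ys, zs))
        without = logistic_assoc(y, x)
        with_cov = logistic_assoc(y, x, covars=z)
        assert with_cov.beta == pytest.approx(without.beta, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()
        res = logistic_assoc(y, x)
        assert not res.estimable


class TestInflation:
    def test_constant_half_gives_one(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_null(self):
        p = np.random.default_rng(6).uniform(size=100000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_doubled_chi2_scales_lambda(self):
        rng = np.random.default_rng(7)
        s = rng.chisquare(1, 100000)
        p = stats.chi2.sf(2 * s, 1)
        assert genomic_inflation(p) == pytest.approx(2.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestBonferroni:
    def test_study_threshold(self):
        thr = bonferroni_threshold(115182, 0.05)
        assert thr == pytest.approx(4.34e-7, rel=0.01)
        assert f"{thr:.1e}" == "4.3e-07"

    @pytest.mark.parametrize("n,alpha", [(1, 0.05), (10, 0.05), (1000, 0.01)])
    def test_closure(self, n, alpha):
        assert bonferroni_threshold(n, alpha) * n == alpha

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestStratifiedFrequency:
    def test_all_controls(self):
        out = genotype_stratified_frequency(np.zeros(30),
                                            np.tile([0, 1, 2], 10))
        assert np.allclose(out["frequency"], 0.0)

    def test_recessive_penetrance_recovered(self):
        rng = np.random.default_rng(8)
        n = 20000
        g = rng.binomial(2, 0.4, n).astype(float)
        spec = rm.DiseaseSimulationSpec(eaf=0.4, or_effect=3.0, n=n)
        y = rm.simulate_disease_status(g, spec, seed=9)
        out = genotype_stratified_frequency(y, g)
        assert out["frequency"].to_numpy() == pytest.approx([0.10, 0.10, 0.25],
                                                            abs=0.02)

    def test_counts_partition(self):
        g = np.array([0, 1, 2, np.nan, 1.0])
        out = genotype_stratified_frequency(np.zeros(5), g)
        assert out["n"].sum() == 4

    def test_empty_class_reported_missing(self):
        out = genotype_stratified_frequency(np.array([1.0, 0.0]),
                                            np.array([0.0, 1.0]))
        assert np.isnan(out.loc[out["dosage"] == 2, "frequency"]).all()
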