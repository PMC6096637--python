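"""Synthetic admixed case-control cohorts.

Generates cohorts with the statistical structure of a two-way admixed
population (an Inuit-like and a European-like ancestry component with
divergent allele frequencies), family relatedness, a recessive-effect
causal variant on a baseline disease risk, and quantitative traits with a
polygenic background.  Every downstream stage of the package is testable
on this output without any data download.

All randomness flows through an explicit integer seed per operation; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AncestryModel",
    "GenotypeMatrix",
    "DiseaseSimulationSpec",
    "sample_ancestry",
    "sample_ancestral_frequencies",
    "sample_genotypes",
    "simulate_disease_status",
    "simulate_quantitative_trait",
    "sample_related_genotypes",
    "simulate_cohort",
    "homozygote_risk",
]

_FREQ_EPS = 1e-6


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass
class AncestryModel:
    """Ancestry proportions Q (n x K, rows on the simplex) and ancestral
    effect-allele frequencies F (m x K, entries in [0, 1])."""

    Q: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.Q.ndim != 2 or self.F.ndim != 2:
            raise ValueError("Q and F must be 2-D matrices")
        if self.Q.shape[1] != self.F.shape[1]:
            raise ValueError(
                f"Q has K={self.Q.shape[1]} components but F has K={self.F.shape[1]}"
            )
        if self.K < 2:
            raise ValueError("admixture semantics require K >= 2")
        if np.any(self.Q < 0) or np.any(self.Q > 1):
            raise ValueError("Q entries must lie in [0, 1]")
        if np.max(np.abs(self.Q.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("every row of Q must sum to 1 within 1e-12")
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ValueError("F entries must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.Q.shape[0]

    @property
    def n_snps(self) -> int:
        return self.F.shape[0]


@dataclass
class GenotypeMatrix:
    """Diploid effect-allele dosages, n individuals x m SNPs.

    Dosages are stored as float with NaN for missing; non-missing entries
    are the integers 0, 1 or 2 (count of the effect allele).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray = None
    effect_alleles: np.ndarray = None
    other_alleles: np.ndarray = None
    chrom: np.ndarray = None
    pos: np.ndarray = None  # 1-based base-pair positions
    iids: np.ndarray = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be an n x m matrix")
        n, m = self.dosages.shape
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosages[~valid][:3]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(m)])
        else:
            self.snp_ids = np.asarray(self.snp_ids)
        if self.effect_alleles is None:
            self.effect_alleles = np.full(m, "A")
        else:
            self.effect_alleles = np.asarray(self.effect_alleles)
        if self.other_alleles is None:
            self.other_alleles = np.full(m, "G")
        else:
            self.other_alleles = np.asarray(self.other_alleles)
        if self.chrom is None:
            self.chrom = np.ones(m, dtype=int)
        else:
            self.chrom = np.asarray(self.chrom)
        if self.pos is None:
            self.pos = np.arange(1, m + 1, dtype=int) * 1000
        else:
            self.pos = np.asarray(self.pos, dtype=int)
        if self.iids is None:
            self.iids = np.array([f"ind{i}" for i in range(n)])
        else:
            self.iids = np.asarray(self.iids)
        for name, arr, expect in (
            ("snp_ids", self.snp_ids, m),
            ("effect_alleles", self.effect_alleles, m),
            ("other_alleles", self.other_alleles, m),
            ("chrom", self.chrom, m),
            ("pos", self.pos, m),
            ("iids", self.iids, n),
        ):
            if len(arr) != expect:
                raise ValueError(f"{name} has length {len(arr)}, expected {expect}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing dosages."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP pooled effect-allele frequency over non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown snp_id: {snp_id!r}")
        return int(hits[0])


@dataclass
class DiseaseSimulationSpec:
    """Parameters of the recessive disease model used in the simulations.

    ``baseline_risk`` is the disease probability for everyone who is not a
    homozygous carrier of the effect allele; homozygotes have the risk
    whose odds are ``or_effect`` times the baseline odds.
    """

    eaf: float
    or_effect: float
    n: int
    baseline_risk: float = 0.1
    model: str = "recessive"

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError("eaf must lie in (0, 1)")
        if self.or_effect <= 0:
            raise ValueError("or_effect must be positive")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.model != "recessive":
            raise ValueError("only the recessive simulation model is supported")


def homozygote_risk(baseline_risk: float, or_effect: float) -> float:
    """Disease probability of homozygous effect-allele carriers.

    The effect is an odds ratio: odds(pi) = OR * odds(baseline), so
    pi = OR*b/(1-b) / (1 + OR*b/(1-b)).
    """
    odds = or_effect * baseline_risk / (1.0 - baseline_risk)
    return odds / (1.0 + odds)


def sample_ancestry(n: int, K: int, mix_params=(3.0, 1.0), seed=None) -> np.ndarray:
    """Draw per-individual ancestry proportions from a Dirichlet distribution.

    The default concentration (3, 1) emulates a cohort with predominantly
    component-1 ancestry (mean 0.75) and a broad spread of admixture
    fractions, as in a two-way admixed Arctic population.

    Returns an (n, K) matrix with rows on the simplex.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if K < 2:
        raise ValueError("K must be >= 2")
    alpha = np.asarray(mix_params, dtype=float)
    if alpha.shape != (K,):
        raise ValueError(f"mix_params must have length K={K}")
    if np.any(alpha <= 0):
        raise ValueError("concentration parameters must be positive")
    Q = _rng(seed).dirichlet(alpha, size=n)
    # guard against denormal rounding so rows sum to 1 within 1e-12
    Q = Q / Q.sum(axis=1, keepdims=True)
    return Q


def sample_ancestral_frequencies(
    m: int, divergence: float = 0.15, base_freqs=None, K: int = 2, seed=None
) -> np.ndarray:
    """Draw ancestral allele frequencies around base frequencies.

    Each component's frequency is a Balding-Nichols draw
    Beta(p(1-d)/d, (1-p)(1-d)/d) around the base frequency p with
    divergence (F_ST-like) parameter d, so Var = d * p * (1-p).  The
    default d = 0.15 produces component gaps on the scale seen between
    Inuit and European frequencies (e.g. 0.31 vs 0.03 at a single SNP).

    Returns an (m, K) matrix clamped to [1e-6, 1 - 1e-6].
    """
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must lie in (0, 1)")
    rng = _rng(seed)
    if base_freqs is None:
        base = rng.uniform(0.05, 0.95, size=m)
    else:
        base = np.broadcast_to(np.asarray(base_freqs, dtype=float), (m,)).copy()
    if np.any(base <= 0) or np.any(base >= 1):
        raise ValueError("base frequencies must lie in (0, 1)")
    scale = (1.0 - divergence) / divergence
    a = base * scale
    b = (1.0 - base) * scale
    F = rng.beta(a[:, None], b[:, None], size=(m, K))
    return np.clip(F, _FREQ_EPS, 1.0 - _FREQ_EPS)


def sample_genotypes(
    Q: np.ndarray, F: np.ndarray, missing_rate: float = 0.0, seed=None, **meta
) -> GenotypeMatrix:
    """Draw genotypes under the admixture model.

    Dosage of individual i at SNP j is Binomial(2, p_ij) with
    p_ij = sum_k Q_ik F_jk (the likelihood used by admixture-proportion
    estimation, with independent SNPs).  Missingness is applied completely
    at random at ``missing_rate``.
    """
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if Q.ndim != 2 or F.ndim != 2 or Q.shape[1] != F.shape[1]:
        raise ValueError(
            f"shape mismatch: Q is {Q.shape}, F is {F.shape}; need Q (n,K), F (m,K)"
        )
    if np.max(np.abs(Q.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("Q rows must sum to 1")
    if np.any(F < 0) or np.any(F > 1):
        raise ValueError("F entries must lie in [0, 1]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = _rng(seed)
    p = Q @ F.T  # (n, m)
    dos = rng.binomial(2, p).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return GenotypeMatrix(dosages=dos, **meta)


def simulate_disease_status(
    dosages_at_causal: np.ndarray, spec: DiseaseSimulationSpec, seed=None
) -> np.ndarray:
    """Simulate binary disease status from dosages at the causal SNP.

    Non-homozygotes are diseased with probability ``baseline_risk``;
    homozygous effect-allele carriers with the probability whose odds are
    ``or_effect`` times the baseline odds.
    """
    g = np.asarray(dosages_at_causal, dtype=float)
    if np.isnan(g).any():
        raise ValueError(
            "missing dosage at the causal SNP; simulate the causal SNP without missingness"
        )
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("causal dosages must be 0, 1 or 2")
    pi_hom = homozygote_risk(spec.baseline_risk, spec.or_effect)
    prob = np.where(g == 2.0, pi_hom, spec.baseline_risk)
    return (_rng(seed).random(g.shape) < prob).astype(int)


def simulate_quantitative_trait(
    G: GenotypeMatrix,
    causal_index: int,
    beta_rec: float,
    grm_background: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Simulate a quantitative trait with a recessive causal effect.

    trait = beta_rec * 1[dosage == 2] + polygenic component + noise.

    The polygenic component is built from the standardized genotypes
    themselves (sum of per-SNP effects drawn i.i.d.), so its covariance is
    proportional to the realized genetic similarity matrix and its variance
    is ~``grm_background``; independent Gaussian noise makes the total
    variance ~1 at beta_rec = 0.
    """
    if not np.isfinite(beta_rec):
        raise ValueError("beta_rec must be finite")
    if not 0.0 <= grm_background < 1.0:
        raise ValueError("grm_background must lie in [0, 1)")
    n, m = G.dosages.shape
    if not -m <= causal_index < m:
        raise IndexError(f"causal_index {causal_index} out of range for m={m}")
    rng = _rng(seed)
    g_causal = G.dosages[:, causal_index]
    hom = (g_causal == 2.0).astype(float)
    trait = beta_rec * hom
    if grm_background > 0:
        X = G.dosages.copy()
        mu = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mu, inds[1])
        X -= mu
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
        w = rng.normal(0.0, np.sqrt(grm_background / m), size=m)
        trait = trait + X @ w
    trait = trait + rng.normal(0.0, np.sqrt(1.0 - grm_background), size=n)
    return trait


def sample_related_genotypes(
    n_families: int,
    family_size: int,
    freqs: np.ndarray,
    seed=None,
) -> GenotypeMatrix:
    """Draw genotypes for sibships to create family relatedness.

    Each family has two unobserved parents with Binomial(2, p) genotypes;
    each of ``family_size`` full siblings receives one allele transmitted
    from each parent per SNP.  Siblings therefore have expected kinship
    1/4 (GRM relationship ~0.5) while families are unrelated.
    """
    if n_families < 1 or family_size < 1:
        raise ValueError("n_families and family_size must be >= 1")
    p = np.asarray(freqs, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("freqs must lie in (0, 1)")
    m = p.size
    rng = _rng(seed)
    mother = rng.binomial(2, p, size=(n_families, m))
    father = rng.binomial(2, p, size=(n_families, m))
    n = n_families * family_size
    # transmitted allele is Bernoulli(parent dosage / 2) per meiosis
    mat = rng.random((n_families, family_size, m)) < mother[:, None, :] / 2.0
    pat = rng.random((n_families, family_size, m)) < father[:, None, :] / 2.0
    dos = (mat.astype(int) + pat.astype(int)).reshape(n, m).astype(float)
    return GenotypeMatrix(dosages=dos)


_COHORTS = np.array(["B99", "IHIT", "BBH"])
_COHORT_PROBS = np.array([0.30, 0.58, 0.12])


def _simulate_ogtt(status: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """OGTT measurements consistent with case/control status.

    Cases draw fasting and 2 h glucose from elevated distributions so that
    the diagnostic thresholds (fasting > 7 mmol/l or 2 h > 11.1 mmol/l)
    are usually met; controls draw from normoglycaemic ranges.  Insulin is
    log-normal; a random half of cases self-report their diabetes.
    """
    n = status.size
    case = status == 1
    fpg = np.where(case, rng.normal(8.6, 1.4, n), rng.normal(5.2, 0.45, n))
    glu2h = np.where(case, rng.normal(13.5, 2.5, n), rng.normal(5.9, 0.9, n))
    fpg = np.clip(fpg, 2.5, 25.0)
    glu2h = np.clip(glu2h, 2.0, 30.0)
    fins = np.exp(rng.normal(np.where(case, 4.4, 3.9), 0.5, n))
    ins2h = np.exp(rng.normal(np.where(case, 5.9, 5.4), 0.6, n))
    weight = np.clip(rng.normal(72.0, 14.0, n), 35.0, 160.0)
    selfreport = case & (rng.random(n) < 0.5)
    return pd.DataFrame(
        {
            "fpg_mmol_l": np.round(fpg, 2),
            "glu2h_mmol_l": np.round(glu2h, 2),
            "fins_pmol_l": np.round(fins, 1),
            "ins2h_pmol_l": np.round(ins2h, 1),
            "weight_kg": np.round(weight, 1),
            "selfreport_dm": selfreport,
        }
    )


def simulate_cohort(
    n: int = 3000,
    m: int = 1000,
    K: int = 2,
    causal_freqs=(0.31, 0.03),
    or_effect: float = 3.0,
    baseline_risk: float = 0.1,
    divergence: float = 0.15,
    missing_rate: float = 0.0,
    mix_params=(3.0, 1.0),
    seed: int = 0,
):
    """Generate a complete admixed case-control cohort.

    The causal SNP (always index 0, id "causal") is drawn without
    missingness with ancestral frequencies ``causal_freqs`` (default: the
    component gap of a common Arctic-specific risk allele, 0.31 vs 0.03);
    disease status follows the recessive odds-ratio model.  Returns
    (GenotypeMatrix, phenotype DataFrame, AncestryModel).
    """
    ss = np.random.SeedSequence(seed)
    s_q, s_f, s_g, s_d, s_p, s_miss = ss.spawn(6)
    Q = sample_ancestry(n, K, mix_params=mix_params, seed=s_q)
    F = sample_ancestral_frequencies(m, divergence=divergence, seed=s_f, K=K)
    F[0, : len(causal_freqs)] = causal_freqs
    G = sample_genotypes(Q, F, missing_rate=0.0, seed=s_g)
    dos = G.dosages
    if missing_rate > 0:
        rng = _rng(s_miss)
        mask = rng.random(dos.shape) < missing_rate
        mask[:, 0] = False  # causal SNP stays complete
        dos[mask] = np.nan
    snp_ids = np.array(["causal"] + [f"snp{j}" for j in range(1, m)])
    G = GenotypeMatrix(dosages=dos, snp_ids=snp_ids)
    pooled_eaf = float(np.nanmean(dos[:, 0]) / 2.0)
    spec = DiseaseSimulationSpec(
        eaf=min(max(pooled_eaf, 1e-6), 1 - 1e-6),
        or_effect=or_effect,
        baseline_risk=baseline_risk,
        n=n,
    )
    status = simulate_disease_status(dos[:, 0], spec, seed=s_d)
    rng = _rng(s_p)
    pheno = pd.DataFrame(
        {
            "iid": G.iids,
            "sex": rng.integers(1, 3, n),  # 1 = male, 2 = female (PLINK coding)
            "age": np.round(rng.uniform(18, 80, n), 1),
            "cohort": rng.choice(_COHORTS, size=n, p=_COHORT_PROBS),
        }
    )
    pheno = pd.concat([pheno, _simulate_ogtt(status, rng)], axis=1)
    pheno["status"] = status
    return G, pheno, AncestryModel(Q=Q, F=F)
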