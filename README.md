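# recessmap

A recessive-model GWAS toolkit for admixed cohorts.

Most genome-wide association studies code genotypes additively (0/1/2
copies of the effect allele).  That coding has poor power against
variants whose risk is confined to homozygous carriers — a situation that
matters in small, historically isolated populations, where recessive
risk alleles for type 2 diabetes can be common and have large effects.
`recessmap` packages the statistical machinery needed to run and study a
recessive-model case-control scan in a two-way admixed population:

* **Cohort simulation** — two ancestry components with Balding–Nichols
  frequency divergence, Dirichlet admixture proportions, HWE genotypes,
  sibship relatedness, a recessive causal variant over a baseline risk
  *b* (homozygote risk π with odds(π) = OR·odds(b)), and OGTT-style
  phenotypes.  PLINK bed/bim/fam and TSV output.
* **Trait derivation** — T2D/NGT classification from fasting and 2 h
  glucose (>7 / >11.1 mmol/l cases, <6.1 and <7.8 controls, strict
  inequalities), HOMA-IR, Gutt's ISI(0,120), and within-stratum
  rank-based inverse-normal transformation Φ⁻¹((r−0.5)/n).
* **Association testing** — per-SNP additive and recessive codings; a
  REML linear mixed model y = Xb + u + e, u ~ N(0, σ_g²K), with the
  genetic similarity matrix K absorbing admixture and relatedness
  (discovery p values), plus covariate-adjusted logistic regression
  (odds ratios); GRM/PCA construction, genomic-inflation diagnostics and
  the Bonferroni threshold (0.05/115,182 ≈ 4.3×10⁻⁷).
* **Power simulation** — the additive-vs-recessive power surface over a
  540-cell (EAF, OR) grid at n = 2948, 20,000 replicates per cell.
* **Ancestry-specific allele frequencies** — admixture proportions by EM
  on the binomial likelihood ∏ Binom(g_ij | 2, Σ_k Q_ik F_jk), then
  per-SNP maximum-likelihood frequencies with Q fixed, with CIs from
  1000 bootstrap resamples of individuals.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Why run a recessive scan at all?  Simulate the headline configuration —
a recessive effect allele at frequency 0.25 with homozygote odds ratio 3
in 2948 individuals at baseline risk 0.1 — and compare test power at the
study-wide threshold:

```python
from recessmap.power import PowerGridSpec, estimate_power

spec = PowerGridSpec(eafs=(0.25,), ors=(3.0,), reps=5000, seed=1)
res = estimate_power(spec, (0.25, 3.0))
print(f"power_recessive = {res.power_recessive:.3f} +/- {res.se_recessive:.3f}")
print(f"power_additive  = {res.power_additive:.3f} +/- {res.se_additive:.3f}")
```

```
power_recessive = 0.781 +/- 0.006
power_additive  = 0.168 +/- 0.005
```

The recessive-coded test finds the variant ~78% of the time; the additive
test, under an identical data-generating process, under 17%.

A full synthetic cohort, with the causal variant common in one ancestry
component (31%) and rare in the other (3%):

```python
import recessmap as rm
from recessmap.ancestry import estimate_component_eaf_table
from recessmap.assoc import genotype_stratified_frequency

G, pheno, model = rm.simulate_cohort(n=3000, m=500, seed=42)
print(estimate_component_eaf_table(G, model.Q, snp_ids=["causal"],
                                   B=1000, seed=42).round(3))
print(genotype_stratified_frequency(pheno["status"], G.dosages[:, 0]).round(3))
```

```
snp_id  eaf_all  ci_all_lo  ci_all_hi   f_1  ci_1_lo  ci_1_hi  f_2  ci_2_lo  ci_2_hi
causal    0.244      0.233      0.254 0.317      0.3    0.334 0.02      0.0    0.052

 dosage    n  n_cases  frequency    se
      0 1714      155      0.090 0.007
      1 1111      102      0.092 0.009
      2  175       49      0.280 0.034
```

The fixed-Q bootstrap recovers both component frequencies (truth 0.31
and 0.03) inside their 95% CIs, and the genotype-stratified disease
frequencies show the recessive signature: ~9% disease among non-carriers
and heterozygotes, 28% among homozygotes.  The corresponding logistic
fit gives OR 3.89, p = 5.7×10⁻¹⁴.

## Command line

```sh
recessmap simulate --n 3000 --m 2000 --seed 1 --out-prefix cohort
recessmap derive-traits --pheno cohort.pheno.tsv --out cohort.traits.tsv
recessmap assoc --bfile cohort --pheno cohort.traits.tsv --model both --out assoc.tsv
recessmap power --eafs 0.25 --ors 1.1:10:0.1 --reps 20000 --out power.tsv
recessmap admixture --bfile cohort --k 2 --out Q.tsv
recessmap ancestry-freq --bfile cohort --q Q.tsv --b 1000 --out freqs.tsv
recessmap run --config pipeline.yaml
```

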