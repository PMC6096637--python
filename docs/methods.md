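# Methods

`recessmap` re-implements, as a tested pipeline, the statistical machinery
of a recessive-model type 2 diabetes (T2D) discovery analysis in a two-way
admixed population: cohort simulation, OGTT-based phenotype derivation,
additive/recessive association testing with a linear mixed model and
logistic regression, an additive-vs-recessive power study, and a two-step
bootstrap maximum-likelihood estimator of ancestry-specific allele
frequencies.  This note records the models, the defaults and the design
choices made where the design was genuinely open.

## Disease model and penetrance

The causal variant acts recessively.  Non-homozygotes have baseline
disease probability *b* (default 0.1); homozygous carriers of the effect
allele have probability π with

    odds(π) = OR · odds(b),   i.e.   π = OR·b/(1−b) / (1 + OR·b/(1−b)).

The effect size is interpreted as an **odds ratio**, because the odds
ratio is the effect measure reported by case-control GWAS.  A
relative-risk interpretation (π = OR·b) is *not* used; at OR 3 and b 0.1
the two differ materially (0.25 vs 0.30) and the odds interpretation is
the one consistent with logistic-regression estimands.

## Power simulation

For each cell of a grid of effect allele frequencies (0.05–0.30 by 0.05)
and odds ratios (1.1–10.0 by 0.1; 540 cells), genotypes of *n* = 2948
individuals are drawn Binomial(2, EAF) under Hardy–Weinberg equilibrium
(HWE is assumed; the data-generating process for the simulation states
nothing else), status is simulated under the model above, and two
maximum-likelihood logistic regressions are fitted per replicate: dosage
coding 0/1/2 and homozygote-indicator coding.  Power per model is the
fraction of 20,000 replicates with two-sided Wald p < 4.3×10⁻⁷ (the
study-wide Bonferroni threshold, 0.05/115,182 SNPs).

Numerical choices:

* The test statistic is the **Wald** chi-square from the ML fit.  A
  likelihood-ratio test differs negligibly at n = 2948; Wald permits a
  closed form for the saturated 2×2 recessive model and a two-parameter
  Newton solve for the additive model, both computed on the aggregated
  3-cell genotype table and vectorised across replicates.  Equality with
  a per-individual `statsmodels` fit is asserted in the test suite, so
  the fast path and the reference route stay independent.
* **Degenerate replicates** (no homozygotes, a zero cell in the 2×2
  table, non-convergence, |β̂| > 30) are assigned p = 1 rather than
  dropped, so power is estimated conservatively.
* The OR axis is built by integer indexing (1.1 + 0.1k, k = 0..89) to
  make the 10.0 endpoint inclusive without floating-point drift.
* Per-cell seeds derive from (grid seed, cell index), so cells are
  independently reproducible.
* No covariates enter the simulation fits.

At the headline cell (EAF 0.25, OR 3) the recessive test has ≈78–80%
power while the additive test stays below 20%, reproducing the rationale
for recessive-model discovery scans.

## Association testing

Discovery p values come from a single-variance-component linear mixed
model; odds ratios come from covariate-adjusted logistic regression.
This split mirrors standard mixed-model GWAS practice, where the binary
status is analysed as a 0/1 quantitative outcome (documented caveat: the
LMM β is on the risk-difference scale, which is why ORs are reported from
the logistic fit instead).

The LMM is y = Xb + u + e with u ~ N(0, σ_g² K) and e ~ N(0, σ_e² I),
where K is the genetic similarity matrix.  A one-time eigendecomposition
K = U S Uᵀ rotates the model to independent observations with variances
σ_e²(λ s_i + 1), λ = σ_g²/σ_e².  λ is estimated by REML via bounded 1-D
optimisation of log λ over [10⁻⁵, 10⁵] (absolute tolerance 10⁻⁶), with
the boundary λ = 0 also evaluated; fixed effects and Wald tests come from
GLS at the optimum.  Per-SNP testing re-optimises λ with the SNP in the
model (exact profile) in `lmm_assoc`; the batch scan `lmm_scan` uses the
null-model plug-in λ, the standard fast approximation.

* **GRM**: mean-imputed, centered cross-product Xc Xcᵀ/m (the documented
  default of widely used mixed-model software); a `standardized` variant
  (unit-variance columns, mean diagonal ≈ 1) is available and is what the
  calibration tests use.  Monomorphic SNPs are dropped.
* **Missing dosages** are excluded case-wise in per-SNP association fits
  (kinship subset accordingly) and mean-imputed in the GRM/PCA and in the
  batch scan, where case-wise deletion would break the shared rotation.
* **PCs** are the top left singular vectors of the standardized
  genotype matrix, sign-fixed so the largest-magnitude loading is
  positive.
* **Genomic inflation** λ_GC = median(χ²₁ quantiles of 1−p)/0.4549.
  On a family-structured null cohort (sibships of four, polygenic trait
  with h² = 0.5) the mixed model keeps λ_GC within [0.95, 1.05] while
  plain regression exceeds 1.1 — the motivation for the mixed model.
* P values are two-sided Wald throughout; perfect separation or constant
  regressors yield flagged, non-estimable results.

## Trait derivation

Diagnostic rules (glucose in mmol/l, strict inequalities): T2D if
self-reported diabetes, fasting glucose > 7, or 2 h glucose > 11.1;
normal glucose tolerance (NGT) if fasting < 6.1 **and** 2 h < 7.8 and no
self-report; everything else — including records too incomplete to
satisfy the control rule — is indeterminate and excluded from
case-control contrasts.  Boundary equality is deliberately neither a case
nor a control, and self-report overrides a measured-normal OGTT (the
precedence is not otherwise defined; overriding is the conservative
choice for a screening definition).

* HOMA-IR = fasting glucose (mmol/l) × fasting insulin (pmol/l)/6.945 / 22.5.
* ISI(0,120) (Gutt): m = (75,000 mg + (G₀−G₁₂₀)×18×0.19×weight)/120 is
  the glucose uptake rate (18 converts mmol/l to mg/dl; 0.19·kg is the
  glucose space); the index is m / mean glucose / ln(mean insulin in
  μU/ml), natural log.  Printed renderings of this formula are often
  typographically garbled; this bracketing is the dimensionally
  consistent published index.  Records whose mean insulin ≤ 1 μU/ml have
  an undefined log and are flagged per record, not fatal to a batch.
* Quantile transform: within each sex × cohort stratum, average ranks r
  map to Φ⁻¹((r − 0.5)/n).  The plotting-position convention is a free
  choice; (r − 0.5)/n is symmetric, keeps odd-stratum medians at exactly
  0, and never produces ±∞.  Strata with fewer than two non-missing
  values are an error naming the stratum.
* Units are enforced at the API boundary and never auto-detected.

## Ancestry-specific allele frequencies

Step 1 estimates admixture proportions Q (K = 2) by EM on the binomial
admixture likelihood ∏ᵢⱼ Binom(g_ij | 2, Σ_k Q_ik F_jk).  The EM updates
are the classical multiplicative ones; because the responsibilities
factor as rank-1 products, each update reduces to matrix products (no
n×m×K intermediates), and plain EM is accelerated by SQUAREM
extrapolation with a monotonicity safeguard, so the recorded
log-likelihood path is non-decreasing.  Convergence: log-likelihood gain
< 10⁻⁴ per accelerated cycle (tunable).  Supervised mode clamps anchor
individuals with known ancestry, which also pins component labels; the
original analysis used ~50 European-ancestry anchors the same way.
Unsupervised fits are label-aligned afterwards against designated
reference individuals.  K = 1 short-circuits to exact per-SNP sample
frequencies.

Step 2 re-estimates, per SNP, the ancestral frequencies f ∈ [0,1]^K with
Q fixed.  The log likelihood is concave in f (the success probability is
linear in f), so the solver runs a few monotone EM warm-up steps and then
damped Newton steps clipped to the box, falling back to an EM step
whenever a Newton step would lower the likelihood; convergence at
log-likelihood gain < 10⁻⁸.  A component with total ancestry mass
Σᵢ Q_ik below one individual-equivalent is flagged non-identifiable (NaN)
rather than estimated.

Confidence intervals resample **individuals** (dosage and Q row jointly)
with replacement, B = 1000 replicates, and take empirical quantiles
(numpy's default linear interpolation); the default level is 95%
((0.025, 0.975)), the level used for published allele-frequency tables.
Replicates in which a component loses identifiability are excluded from
that component's quantiles with a reported count.  Coverage at the
tabulated Inuit/European frequency gap (0.31 vs 0.03, n = 3000) is
~93% jointly across both components in the test suite's repeated-
simulation experiment.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume:

* **Ancestry** Q ~ Dirichlet; default concentration (3, 1), i.e. mean
  75%/25% with a broad spread, resembling a predominantly Inuit cohort
  with European admixture.
* **Ancestral frequencies** are Balding–Nichols draws around a base
  frequency with divergence d (Var = d·p(1−p)); default d = 0.15 yields
  component gaps on the scale of 0.31 vs 0.03.  The unadmixed-group
  recovery experiments use d = 0.3 (strongly differentiated panels), the
  regime in which per-individual ancestry is identifiable to ±0.05 from
  2000 SNPs.
* **Genotypes** g_ij ~ Binomial(2, Σ_k Q_ik F_jk), independent SNPs (no
  LD).  Missingness, when requested, is completely at random.
* **Family structure** comes from sibships: two latent parents per
  family, one transmitted allele per parent per SNP (sibling genotype
  correlation 1/2).
* **Quantitative traits**: β_rec·1[g=2] + a polygenic component built
  from the standardized genotypes (covariance proportional to the
  realized GRM, variance = `grm_background`) + Gaussian noise, total
  variance ≈ 1.
* **OGTT values** are drawn from case/control-conditional distributions
  so that the diagnostic thresholds reproduce the simulated status for
  >90% of cases; half of cases self-report.

What the generator does **not** emulate: linkage disequilibrium,
haplotype/coalescent structure, sex-specific or X-linked effects,
informative missingness, assay error, or real pedigrees.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those features of real data.

## Problem sizes in the test suite

Tests run the methods at sizes chosen to keep the full suite in a few
minutes while leaving Monte-Carlo error well below the asserted
tolerances: power checks use 1500–5000 replicates per cell (the
acceptance script uses the full 20,000), the mixed-model calibration
cohort is 600 individuals × 20,000 null SNPs, bootstrap-coverage
experiments use 50 simulations × 1000 bootstrap replicates at n = 3000,
and EM recovery runs at n = 400–500, m = 1000–2000.

## Known limitations

* The LMM analyses binary status as a 0/1 outcome (as standard
  mixed-model GWAS software does); no liability-scale transformation.
* `lmm_scan` uses the plug-in variance ratio; exact per-SNP profiling is
  available per SNP but not vectorised.
* Ancestry-specific odds ratios (ancestry-aware effect-size models) are
  out of scope; only ancestry-specific allele frequencies are estimated.
* K > 2 admixture is supported by the math but exercised only at K = 2.
* The power study covers the binary trait only; no analytic power
  formulas are provided.
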