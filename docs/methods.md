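# Methods

This note documents the statistical models implemented in `t2domics`, the
design of the synthetic cohorts the test suite runs on, the numerical
choices that matter, and the known limitations. Nothing here states an
empirical result the tests or `scripts/acceptance.py` do not themselves
compute.

## Study design being modeled

The pipeline reproduces a multi-omics inference chain for type 2 diabetes
(T2D): a blood-methylation EWAS over two cohorts with a two-way
discovery/replication design, methylation-QTL mapping of the selected CpGs
against whole-genome variants under a kinship mixed model, a metabolome-wide
association study with a Bonferroni discovery/replication split, a two-batch
CpG–metabolite meta-analysis, two-sample Mendelian randomization (MR) of
methylation on HbA1c from summary statistics, and a tripartite
SNP–CpG–metabolite network built on a Gaussian-graphical-model (GGM)
metabolite backbone.

## EWAS

Per CpG, the methylation beta value (bounded in [0, 1]) is the dependent
variable in an OLS regression on disease status with covariates: sex, two
principal components of the five lab cell counts, plate, profiling batch, a
batch-by-sex interaction, sample well position (a single categorical
factor), the AHRR-type smoking-surrogate CpG, and three genomic principal
components from standardized dosages. Models are fitted with and without
BMI.

**Age** is not a design column. Because cases are systematically older than
controls in the cohorts modeled here, age is handled by a two-step residual
method: each CpG is regressed on age *in controls only* and the fitted
(β₀, β₁) line is subtracted from every sample. A consequence worth knowing:
the age slope is estimated with noise, and under strong age–disease
collinearity that estimation noise is partially aligned with the disease
contrast, which leaves residual test-statistic inflation (genomic inflation
λ ≈ 1.2–1.7 in our experiments depending on how the age line is fitted).
The inflation ratio does not vanish with sample size — it scales with the
squared age–disease correlation and the ratio of tested samples to
age-model controls. The calibration tests therefore run on an
exchangeable-label null (no disease–age association, see *Synthetic
cohorts*), which isolates the correctness of the regression machinery; the
residual-method inflation under the collinear design is a documented cost of
the adjustment, mitigated in practice by the stringent epigenome-wide
threshold.

**Selection.** CpGs at p < 5.8×10⁻⁸ in one cohort are tested in the other
at 0.05/k (k = that pass's discovery count); the procedure is repeated with
the cohorts swapped and the passes unioned, tagging each CpG with its more
significant discovery cohort. The with- and without-BMI selections are then
unioned and only CpGs whose effect has the same sign in both cohorts are
kept. Two-sided p-values throughout; complete-case analysis per model.

The scan is implemented as batched linear algebra (QR residualization of
both sides against the shared covariate design; Frisch–Waugh), verified
against statsmodels OLS on random instances. When a design is restricted to
one cohort, indicator columns that become constant or aliased (e.g. a
batch-by-sex interaction inside a single-batch cohort) are pruned greedily
by rank.

## meQTL mapping

Per CpG the polygenic model y ~ N(Xβ, σ²_g·2K + σ²_e·I) is fitted by
maximum likelihood, profiling the heritability ratio h² = σ²_g/(σ²_g+σ²_e)
over [0, 1) on the spectral decomposition of the genomic relationship
matrix 2K (one eigendecomposition per sample set; bounded scalar
minimization with xatol 10⁻⁶; a boundary fit at h² = 0 is accepted when the
interior optimum is no better, and reduces exactly to OLS). K is half the
GRM computed from centered, allele-frequency-scaled dosages averaged over
polymorphic SNPs, with negative eigenvalues bent to 10⁻⁶. ML rather than
REML keeps the profile one-dimensional and verifiable against a grid
oracle; with n ≫ rank(X) the difference is negligible for the score test.

Each SNP is tested with the mixed-model score statistic
T = (g̃ᵀV⁻¹r)²/(g̃ᵀV⁻¹g̃) against χ²₁, where g̃ is the centered genotype and r
the polygenic residuals; the reported effect is b = (g̃ᵀV⁻¹r)/(g̃ᵀV⁻¹g̃) with
SE = (g̃ᵀV⁻¹g̃)^(-1/2). SNPs with MAF ≤ 0.01 are skipped. The covariate set
adds disease status, BMI and age to the EWAS technical covariates.

Pairs at p < 8.7×10⁻¹⁰ are kept and labeled **cis** when SNP and CpG share
a chromosome at a distance strictly below 1 Mb, **trans** otherwise
(including same-chromosome pairs at or beyond 1 Mb — the cis definition is
exclusive). A discovery pair **replicates** when the replication split
(defined by genotyping batch) shows the same CpG at the identical SNP or at
any SNP within ±500 kb passing 0.05/n_discovery (threshold configurable;
the source design does not print one).

## Metabolomics

**QC**: natural-log transform (the base is irrelevant after
standardization), a single-shot outlier pass masking values beyond ±3 SD of
each metabolite's log distribution, re-standardization to mean 0 / SD 1,
and removal of zero-variance metabolites (with a relative tolerance of
10⁻¹² so float dust does not count as variance) and metabolites with more
than 20% missingness (configurable; the source design is silent). The
outlier pass is deliberately not iterated; re-applying QC to its own output
is the identity except that genuinely heavy-tailed panels can re-trigger
the ±3 SD rule after re-standardization, which is the expected behavior of
a single-shot trim.

**MWAS**: metabolite ~ disease status with age, sex, BMI and three genomic
PCs, over a seeded random 70/30 discovery/replication split. Discovery
keeps p < 0.05/m (m = panel size); replication keeps p < 0.05/k with a
concordant sign.

**CpG–metabolite meta-analysis**: the EWAS model without BMI, CpG
dependent, run separately in two profiling batches; fixed-effect
inverse-variance combination (METAL's STDERR scheme): weights 1/SE²,
combined SE (Σw)^(-1/2), two-sided normal p, Cochran's Q against χ²_{df},
I² = max(0, (Q−df)/Q)·100. Pairs with heterogeneity p < 0.05 are excluded;
with two batches this is *exactly* equivalent to Q > 3.841 and to
I² > 73.96% — the empirical "I² > 74" correspondence is a theorem of the
df = 1 inverse-variance case, and the test suite proves it property-wise.
Selection keeps meta p < 0.05/(n_cpgs·n_metabolites) before the
heterogeneity filter.

## Mendelian randomization

Inputs are per-SNP summary statistics (Bx, Bxse) for SNP→CpG (cohort meQTL
scale: methylation is the exposure) and (By, Byse) for SNP→HbA1c from GWAS
databases; the packaged table `t2domics/data/mr_hba1c_inputs.tsv` carries
the HK1 (cg08992189, three variants) and PFKFB2 (cg22699725, one variant)
rows used as worked examples.

* **Wald ratio**: By/Bx.
* **Single-SNP ML**: maximize the bivariate normal likelihood
  Bx ~ N(ξ, Bxse²), By ~ N(θξ, Byse²) over (ξ, θ) numerically
  (Nelder–Mead); the MLE of θ equals the Wald ratio analytically, and the
  Fisher-information SE equals the second-order delta expression
  √((Byse/Bx)² + (By·Bxse/Bx²)²). Both identities are enforced in tests
  against the numerical path (1,000-case random grid, within 1%).
* **IVW**: fixed-effect combination of per-SNP ratios with first-order
  weights s_j = Byse_j/|Bx_j|. First-order (not second-order) weights are
  used deliberately: they reproduce the published combined SE for the
  three-variant HK1 analysis, which second-order weights do not. Q is
  computed over J−1 df with I² reported alongside.

Confidence intervals are estimate ± 1.96·SE with two-sided normal p. The
published heterogeneity "score" for the HK1 combination is interpreted as
Cochran's Q (df = 2), since exp(−Q/2) reproduces the published
heterogeneity p exactly; I² proper is additionally reported. Because the
published inputs carry only 3–4 significant figures, recomputed p-values
match to ~1% rather than exactly.

## Network

Metabolite residuals (after the MWAS covariate set — the "covariates
mentioned previously" are taken to be the metabolite model's own set;
configurable) are summarized by a correlation matrix shrunk toward the
identity with the analytic Ledoit–Wolf/Schäfer–Strimmer intensity; partial
correlations come from its inverse via pcor_ij = −P_ij/√(P_ii·P_jj); edges
are tested by Fisher z with effective sample size n − (p−2) − 3 and kept
below 0.05 divided by all p(p−1)/2 metabolite pairs (the Bonferroni
denominator counts all pairs among included metabolites). This replaces the
empirical-Bayes local-fdr edge test of the GeneNet package with a
verifiable z-approximation under the same Bonferroni philosophy; at n ≫ p
the shrunk partial correlations match the exact inverse-correlation
computation to 10⁻³. The intensity estimator builds an n×p×p array, which
is fine for the panel sizes used here (p ≤ 60) but would need a streaming
variant for panels of hundreds of metabolites.

SNP–CpG (meQTL), CpG–metabolite (meta-analysis) and metabolite–metabolite
(GGM) edges are unioned into one undirected typed graph; node layers are
inferred from edge types and conflicts raise; duplicate edges keep the
smaller p. Components are reported by size. Exports: SIF, GraphML, and
Cytoscape-loadable node/edge TSVs.

## Synthetic cohorts

The generator produces the joint structure the stages assume, with ground
truth recorded for recovery tests.

* **Genotypes**: two ancestry components with Balding–Nichols divergence
  (Fst 0.01, an arbitrary but declared population-stratification choice),
  MAF uniform on [0.05, 0.5], SNPs laid out over four chromosomes spanning
  up to 240 Mb. Families are explicit sib groups — parental haplotypes are
  drawn and each sib inherits one haplotype per parent per SNP — so kinship
  estimation is genuinely exercised (expected GRM entry 0.5 between sibs).
* **Phenotypes**: 43% cases; the case rule has the cohort-design shape
  (self-reported diagnosis OR HbA1c ≥ 6.5, onset above 30) and is enforced
  by construction. Cases are older than controls in cohorts 1–2 (means
  53.5 vs 36.0; cohort 3 ages overlap) — the `age_collinear_t2d` switch
  disables this for exchangeable-label null cohorts. BMI differs by case
  status; cell counts are Dirichlet compositions; plate, well row, three
  profiling batches, a genotyping-batch split (68.5%/31.5%) and a
  metabolomics batch split are assigned.
* **Methylation**: beta values are the inverse logit of a linear predictor
  over SNP dosage, disease status, age, sex, batch, batch-by-sex,
  cell-count contrasts, a latent smoking variable driving the surrogate
  CpG (prevalence 0.2, effect −1.5 logits), and N(0, 0.4) logit noise.
  Planted effect sizes (logit scale): disease effects 0.2–0.35, SNP
  effects 0.4–0.5 — chosen so the derived beta-scale effects (~0.04–0.1)
  sit in the range real EWAS hits occupy and are detectable at the study's
  sample sizes. Ground truth records beta-scale estimands as exact
  finite-difference contrasts through the logistic link at the realized
  linear predictors.
* **Metabolites**: a sparse precision matrix with unit diagonal, 10% edge
  density and partial correlations of magnitude 0.25–0.45 (typical of
  metabolomics GGMs), rescaled if needed to keep the smallest eigenvalue
  above 0.05; multivariate-normal draws with covariance equal to its
  inverse; planted disease shifts and CpG links in units of each
  metabolite's own marginal SD; exponentiation to a positive raw scale
  (log-SD 0.35) so the QC log-transform is meaningful; 1% missingness.

What the generator does **not** emulate: linkage disequilibrium beyond
independent SNPs, array-level artifacts (the pipeline consumes
post-normalization beta values by design), non-Gaussian metabolite tails,
and medication effects. Passing tests therefore demonstrate the statistical
machinery and the selection logic, not robustness to those real-data
features.

Recovery fixtures plant *disjoint* targets (the direct disease shift and
the CpG link act on different metabolites): when one metabolite carries
both, the MWAS "recovers" direct-plus-indirect effect because the linking
CpG is itself disease-driven — a real identification issue, not an
estimator defect. The pipeline's default panel keeps the overlapping design
(a metabolite both disease- and methylation-associated is realistic) for
end-to-end runs.

## Problem sizes and determinism

Test and driver runs use study-scale cohorts of 900 samples × 300 CpGs ×
2,000 SNPs × 60 metabolites (recovery fixtures: 2,000 samples with smaller
panels; calibration: 2,000 null CpGs / 2,000 null SNPs; GGM recovery: 20
panels of 30 metabolites × 800 samples) — large enough for the asymptotics
the checks rely on while keeping a full run in minutes on one CPU. All
randomness flows from explicit integer seeds through numpy Generators;
identical configuration and seed reproduce byte-identical outputs, and the
pipeline writes per-stage manifests with input hashes, seeds, thresholds
and counts.

## Known limitations

* The two-step age-residual adjustment leaves residual inflation under
  age–disease collinearity (quantified above); interpret nominal EWAS
  p-values near the threshold accordingly.
* Single-SNP MR p-values computed from rounded published inputs match the
  published values approximately, not exactly.
* The mmscore-type test is a score test: its small-sample behavior differs
  from the exact GLS Wald test at O(1/n) (tested to 5% agreement at h²=0).
* Metabolite missingness is mean-imputed per metabolite before the GGM
  projection; at the simulated 1% missingness this is immaterial, at high
  missingness it would attenuate partial correlations.
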