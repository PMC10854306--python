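# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic cohorts do and do not emulate, and the numerical
decisions a maintainer would want to know. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Composite phenotypes

Raw fields per donor: CERAD (neuritic plaque, canonical 1–4 coding where 1 =
no plaque), Braak stage (0–6), CDR (0, 0.5, 1–5), five regional amyloid-β
plaque densities, ApoE genotype, and six exclusion-diagnosis flags
(psychiatric disorder; neurodegenerative disease other than AD/FTD; systemic
autoimmune disease; brain cancer; sepsis as cause of death; severe
alcoholism).

Label rules and choices:

* **AD (CERAD)**: case if CERAD ≥ 2, control if CERAD = 1. Some cohorts
  code CERAD 0–3; the `cerad_coding="0-3"` option maps those inputs by +1.
* **AD (clinical)**: case requires CERAD ≥ 3, Braak ≥ 3 and dementia
  (CDR ≥ 1); control requires CERAD = 1, Braak ≤ 2 and CDR = 0. Either
  rule tolerates **one** missing component provided the observed components
  hold; donors with all three missing are `missing`; everyone else is
  `other`.
* **Exclusions take precedence**: any set flag makes both AD diagnoses
  `other`, even when clinical fields are missing. Missing flag values (or a
  missing flag column) are treated as False with a logged warning — absence
  of evidence of a disqualifying diagnosis is not treated as one.
* **Dementia (CDR)**: case iff CDR ≥ 1; CDR 0.5 (MCI) is neither case nor
  control and is kept on the harmonized 0 / 0.5 / 1 cognitive scale
  (CDR 1–5 collapse to 1).
* **Quantitative measures**: `amyloid_mean` averages the *available*
  regional densities (a donor missing one region still gets a mean; only
  all-missing yields missing); `apoe4_count` counts ε4 alleles;
  `braak_class` is high ≥ 5, low ≤ 2, mid otherwise.
* **Age gate**: `eligible` defaults to age ≥ 45 years, the conventional cut
  between early-onset/other pathology and the late-onset cohorts these
  analyses target. It is reported, not silently applied.

## Expression preparation

* **Abundance filter**: keep features with CPM (or TPM, given lengths)
  strictly greater than the threshold in at least `ceil(fraction × n)`
  samples, computed on raw library sizes — filtering precedes normalization.
  `ceil` makes the rule conservative and deterministic (10 samples at 15%
  requires 2). The operation is idempotent.
* **TMM**: trimmed mean of M-values with the canonical trim fractions, 30%
  on M (log ratio) and 5% on A (average abundance), delta-method precision
  weights, and the reference sample chosen as the one whose upper-quartile
  relative abundance is closest to the mean upper quartile. Factors are
  rescaled to geometric mean 1. With a single usable feature the trimming is
  degenerate and factors fall back to library-size-only (all 1) with a
  warning. The implementation reproduces edgeR's `calcNormFactors` to ~1e-6
  on a frozen fixture (see `tests/test_prep.py`).
* **Precision weights**: log2-CPM is
  `log2((count + 0.5) / (effective_lib + 1) × 1e6)`; per-feature residual
  square-root SDs from an OLS fit are regressed on average log-count with a
  lowess smoother (span 0.5) and each observation's weight is
  `1 / sd_hat⁴` at its fitted count. Beyond the trend's range the prediction
  is held constant (a monotone extrapolation); predicted square-root SDs are
  floored at 1e-4 so weights stay finite and positive.
* **Sample QC**: a sample is an expression outlier when its mean correlation
  with all other samples falls more than 3 SDs (configurable) below the
  across-sample mean of that statistic. Single pass — no iterative
  re-screening, since removing one outlier and rescreening can cascade.

## Differential expression

Per feature, weighted linear regression of log2-CPM on an intercept,
covariates and the phenotype contrast, with the source biobank as a random
intercept:

* The REML criterion is profiled over the variance ratio λ = τ²/σ² and
  minimized by bounded scalar search on log λ (with an explicit λ = 0
  boundary check); the Woodbury identity keeps each evaluation O(n·q).
* With fewer than **3** source levels the random intercept is not
  estimable with any stability and the fit silently reduces to weighted
  least squares (with a warning at 2 levels). A single-level random group
  therefore reproduces the fixed-effects fit exactly.
* Degrees of freedom for the contrast use a **Satterthwaite-style**
  approximation from the expected REML information of (σ², τ²), clamped to
  [1, n − p]. Calibration — not numerical identity to any particular mixed
  -model implementation — is the contract, and is verified by simulation:
  at 180 donors, 2000 genes and source SD 0.5 the null p ≤ 0.05 fraction
  and the BH empirical FDR are asserted in `tests/test_acceptance.py`.
* No empirical-Bayes moderation of residual variances is applied; each
  feature uses its own.
* Binary contrasts are two-level factors (control = 0); ordinal phenotypes
  (CERAD 1–4, Braak 0–6) default to numeric linear scores; both encodings
  are explicit in `DesignSpec`.
* Features whose fit fails (singular weighted design, zero variance) are
  reported with NaN statistics and a reason code; the run continues and BH
  is applied over the successful fits only.

**π₁ (Storey)**: π₀(λ) = #{p > λ} / (n(1 − λ)) over λ = 0.05…0.95 is
smoothed with a cubic least-squares fit and read off at λ = 0.95. The fit is
precision-weighted by √(1 − λ) because the binomial variance of the tail
count grows like 1/(1 − λ); this materially stabilizes the estimate at the
grid's right edge, where the plain cubic is noisy. Results are clipped to
[0, 1].

## Transcript-level omnibus tests

Per gene with m transcripts: effects β, standard errors (D = diag se), and a
statistic correlation Σ estimated from the Pearson correlation of the
transcripts' *residual expression* profiles from the same fitted DE model —
the standard proxy for the correlation of the test statistics themselves.
The estimate is shrunk toward identity, `Σ = (1 − s)R + sI` with s = 0.05,
to guard positive definiteness at small n (eigenvalues are additionally
floored at 1e-8 and the matrix renormalized to unit diagonal).

With V = DΣD:

* **FE** (concordance): pooled mean `μ = (1ᵀV⁻¹β)/(1ᵀV⁻¹1)`, statistic
  `S_mean = μ²(1ᵀV⁻¹1)`.
* **RE2C-style joint test**: `S_het = (β − μ1)ᵀV⁻¹(β − μ1)`;
  statistic `S_mean + S_het`; heterogeneity fraction
  `S_het / (S_mean + S_het)` (0 when all β equal; for m = 1 the joint test
  is the Wald test and the fraction is 0).

**Null references.** Given only summary-level inputs the references are
χ²₁ for FE and, for the joint statistic, a weighted-χ² moment-matching
approximation (Liu-type) on the eigenvalues of the implied quadratic form —
which are identically 1 under the estimated covariance, so the joint null is
χ²_m. When the per-transcript residual degrees of freedom ν and the
unshrunk correlation estimate are available (the data-level pipeline), the
tests instead use a finite-sample reference: the estimated covariance is
effectively Wishart with ν degrees of freedom, making the exact null of a
GLS contrast a Hotelling-type F — `S_mean(ν−m+1)/ν ~ F(1, ν−m+1)` and
`(S_mean+S_het)(ν−m+1)/(νm) ~ F(m, ν−m+1)` — with a first-moment rescaling
for the deliberate shrink distortion (FE: the scalar
`(1ᵀΣ_s⁻¹Σ_uΣ_s⁻¹1)/(1ᵀΣ_s⁻¹1)`; joint: `m / tr(Σ_s⁻¹Σ_u)`). The
large-sample χ² references are measurably anti-conservative at n = 100 with
estimated SEs and correlations; the finite-sample reference restores size
(verified at 5000 replicates in the acceptance suite). The statistics are
unchanged either way.

**Classification** (gene-level vs omnibus): BH is applied within each
analysis separately over the shared genes; a gene is `gene_only`,
`omnibus_only`, `both` or `neither` by FDR ≤ 0.05 in each. The
heterogeneous pattern of interest — one transcript of opposite sign
cancelling in gene-level read summing while driving `S_het` — is generated
by the synthetic cohorts and asserted to land in `omnibus_only` in a
majority of replicates.

## Differential correlation

For anchor gene a and each partner y, the model is
`y ~ slope_case·(a_res·case) + slope_control·(a_res·control) + intercept +
covariates`, where `a_res` is the anchor residualized on the covariates —
a literal two-slope reading of a nested-interaction formula. The p-value is
the Wald test of `slope_case = slope_control`. Direction calls compare
|r_case| and |r_control| computed on covariate-residualized expression
within each group. The voom precision weights are reused by default (each
partner's fit is then per-feature WLS); with no weights and no random group
the scan is a single vectorized multi-response OLS. The anchor is excluded
from the partner list; partners constant within a group are dropped with a
warning. Summaries: Storey π₁ over the scan's p-values and the fraction of
significant partners (at p ≤ 0.05 and FDR ≤ 0.05) whose correlation is
stronger in controls — reported as missing when nothing is significant.

## Gene sets and modules

* **Competitive enrichment** is the parametric two-sample form: in-set vs
  out-of-set mean statistic, pooled variance, with the in-set variance term
  inflated by VIF = 1 + (m − 1)ρ. ρ defaults to 0.01; at ρ = 0 the test is
  exactly the equal-variance two-sample t-test.
* **Fisher overlap** uses the hypergeometric 2×2 test; the reported odds
  ratio is the sample OR with a Haldane 0.5 correction only when a cell is
  empty.
* **Per-sample composite scores** use an unweighted Kolmogorov–Smirnov-style
  hit/miss random walk on each sample's descending gene ranking (signed
  maximum deviation), up-set score minus down-set score. This is a
  deliberately simplified single-sample variant rather than the
  kernel-density GSVA estimator: only the relative ordering of samples is
  consumed downstream, and rank invariance to monotone transforms is the
  property that matters (asserted in tests).
* **Module annotation**: functional signatures (rows of a −log₁₀ p
  enrichment matrix over modules) are clustered with average linkage on
  Euclidean distance — a standard, deterministic choice. k is the smallest
  cluster count whose cluster sizes all fall within configured bounds
  (default 0.2%–25% of signatures); an all-singleton cut is rejected as
  degenerate. Each module takes the cluster of its most-enriched signature.
  Cluster labels are the top 1–3 name tokens by one-sided Fisher enrichment
  of the cluster's signature names against all names, after splitting on
  underscores and dropping collection prefixes and stopwords.
* **Key drivers**: intersection of (a) DE significance (BH ≤ 0.05), (b)
  membership in a module enriched for the signature, (c) presence in the
  module's externally supplied hub list. Hub detection itself is out of
  scope; hub lists are inputs.

## Trajectory

The consumed outputs of a reverse-graph-embedding tree — a spanning tree,
sample projections, geodesic pseudotime, branches — are fully specified
without the original optimization, so the implementation is deliberately
lightweight ("DDRTree-lite"): PCA to d = 2 (d is configurable; 2 matches
what downstream plots and cluster cuts use), k-means centroids as tree nodes
(default `min(50, n_samples // 3)` — enough resolution for percent-level
pseudotime granularity without overfitting noise), minimum spanning tree
over the centroids with Euclidean weights, and exact nearest-point-on-edge
sample projection. The ordering/branch-recovery contract is verified by
simulation, not by numerical identity to any reference tool.

* **Signature panel**: per contrast and direction (sign of log2FC), genes
  rank by p ascending with ties broken by |log2FC| descending then by id;
  the top N (default 100) per direction union across contrasts, with
  provenance retained.
* **Root**: one endpoint of the tree's maximum-diameter path (brute-force
  over node pairs with deterministic tie-breaks). With per-sample severity
  scores supplied, the endpoint whose nearer samples have the lower mean
  score becomes the root (so pseudotime increases with severity); otherwise
  the lower node id — arbitrary but deterministic.
* **Pseudotime**: geodesic tree distance from the root to each sample's
  projection point (offset along its edge included).
* **Branches**: maximal paths between nodes of degree ≠ 2; a sample takes
  its projection edge's branch. **Clusters**: remove the n−1 largest tree
  edges and take components; a sample joins the component of its edge's
  nearer endpoint. Cluster ids are canonicalized by ascending mean
  pseudotime so repeated runs label identically.
* **Cluster characterization**: two-sided Wilcoxon rank-sum tests of scores
  or metadata between cluster pairs; pairs with under 3 samples are skipped
  with a reason, constant comparisons reported as missing.

## Synthetic cohorts

The generator produces what the analyses assume, with truth tables:

* **Donors**: age ≈ N(80, 9) with a small young tail, sex, 3 source
  biobanks (60/25/15%), 3 Gaussian technical covariates, log-normal PMI.
* **Phenotypes** derive from one latent severity score per donor with an
  age slope calibrated so `age_confounding` (default 0.02/year) is
  approximately the slope of case probability on age near the cohort
  median. CERAD, Braak and CDR are independently noised copies of the
  severity thresholded at fixed level fractions — giving the positive mutual
  rank correlations real AD metrics show without copying any real
  distribution. Regional amyloid densities are non-negative transforms of
  severity; ApoE ε4 allele frequency is weakly coupled to severity.
  CERAD ≥ 2 *is* the expression-effect carrier, so the disease indicator and
  the AD (CERAD) label coincide by construction. Missingness: ~3% per
  ordinal phenotype, 10% of donors lack the amyloid assay, 5% lack
  genotypes. Exclusion flags fire at 2% each.
* **Counts**: per gene, 1–5 transcripts with Dirichlet abundance shares;
  transcript log2-expression = baseline + disease effect × case + technical
  and sex effects + per-source random intercept (SD 0.5, the level the DE
  calibration scenario states) + a per-gene latent factor giving within-gene
  transcript equicorrelation `transcript_cor` (default 0.6) at scale
  `biological_sd` (default 0.7 log2 units — typical bulk biological CV).
  Counts are gamma-Poisson (variance μ + φμ², φ log-normal around 0.1), and
  **gene counts are the sum of their transcript counts**. Means are scaled
  by a *fixed* normalizer (the baseline expression total) rather than the
  per-sample realized total, so planted log2 fold changes are exactly the
  log-mean differences and recovery tests are not biased by compositional
  renormalization; at the default 10% affected fraction with zero-mean
  effects the difference from per-sample normalization is negligible.
* **Heterogeneous genes**: a fraction (default 0.2) of affected multi-
  transcript genes flip exactly one transcript's effect sign. The recorded
  gene-level truth is the abundance-weighted log2 ratio
  `log2(Σ wₜ 2^βₜ)`, which equals β for concordant genes.
* **Trajectories**: a trunk of length L/2 splitting into `n_branches`
  branches (a single branch is one unbroken path). Responsive genes vary
  linearly in position on the log2 scale, with the trunk slope continuing
  into a branch-specific slope (continuous at the split, monotone within
  each branch). Truth records position and branch.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no read- or isoform-structure (no splicing,
no length/GC effects, no positional bias); equicorrelated transcripts only
(real isoform correlation is structured); independent genes apart from the
within-gene factor (no co-expression network, so FDR behaviour under strong
inter-gene correlation is untested); phenotype noise is Gaussian-threshold,
not the heaped/censored distributions of real clinical scales; technical
covariates are independent Gaussians rather than correlated QC metrics; and
the case indicator is exactly CERAD-derived, whereas real diagnosis labels
carry error.

**Problem sizes.** The acceptance suite uses the sizes its scenarios state:
1000 random pooling problems; 5000 replicates of the m = 4, ρ = 0.6,
n = 100 correlated null; 1000 power replicates and 200 classification
replicates; one 180-donor × 2000-gene cohort per DE condition; 10,000
p-values for π₁; 500 partners / 100 seeds for differential correlation; 150
samples for trajectory recovery. These run in well under a minute in total
on one CPU and give Monte-Carlo error comfortably inside the asserted
tolerances.

## Numerical conventions

* p-values are floored at the smallest positive double; FDR columns are BH
  step-up with monotonicity (via statsmodels `multipletests`).
* Correlation matrices are symmetrized implicitly by construction;
  positive definiteness is enforced by eigenvalue flooring + diagonal
  renormalization. Zero-variance residual rows get zero correlation with a
  warning rather than an error (the gene is still testable).
* Deterministic tie-breaks throughout: stable lexicographic sorts for
  ranking, node-id ordering for diameter endpoints and default roots,
  (weight, node ids) ordering for tree-edge cuts.
* All randomness flows from a single `numpy.random.default_rng(seed)` per
  generator call; identical (config, seed) pairs are byte-identical on
  disk.

## Known limitations

* The Satterthwaite approximation can be optimistic for severely unbalanced
  source groups at q = 3; the calibration suite covers the balanced-to-
  moderately-unbalanced designs the generator produces.
* The differential-correlation model omits a group main effect (the
  two-slope formula); if groups differ in partner mean *and* the anchor
  distribution differs by group, slope differences can absorb mean
  differences. Including the group among the covariates restores the
  adjustment when that matters.
* `storey_pi1` remains noisy below ~500 p-values (it warns under 100).
* The trajectory tree is fitted in the PCA plane; strongly nonlinear
  manifolds that fold in 2-D would need a larger `d`.
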