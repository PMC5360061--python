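# Methods

## The question and the model

A gene measured in blood drawn years before a CLL diagnosis can differ
between future cases and controls because it marks susceptibility, an early
biological effect, or disease already present at low burden.  Comparing the
prediagnostic signal gene-by-gene with the signal seen in diagnosed patients
separates these readings: markers present in both settings point to early
disease, markers exclusive to the prediagnostic setting to susceptibility or
progression imprints.  `premeta` implements the comparison as two fitting
stages feeding a classification and a set of structure analyses.

### Harmonization

Public clinical expression studies arrive on different platforms with
different (often unknown) preprocessing.  Each probe's values are mapped to
normal scores by a rank-based inverse normal transformation with the Blom
offset, Φ⁻¹((r − 3/8)/(n + 1/4)), with mid-ranks for ties; probes are then
collapsed to genes by the median normalized value, and the analysis is
restricted to genes measured in every study.  The transform is applied per
gene across the samples of one study (the downstream effect sizes compare
case and control distributions gene-wise); a per-array mode exists behind
`int_axis="sample"` for sensitivity analyses, since either axis is
defensible.  Normalization precedes collapsing so that probe-level scale
differences never reach the median.

### Clinical arm: random-effects meta-analysis

Per gene and study the effect is the Hedges-corrected standardized mean
difference d = J (x̄₁ − x̄₀)/sₚ, J = 1 − 3/(4(n₁+n₂−2) − 1), with
large-sample variance v = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)).  Studies are
pooled per gene by DerSimonian–Laird random effects: fixed weights w = 1/v
give Cochran's Q; τ̂² = max(0, (Q − (S−1))/(Σw − Σw²/Σw)); random-effects
weights w* = 1/(v + τ̂²) give the pooled μ, its standard error and a
two-sided normal p-value.  Q is referred to χ²(S−1) for heterogeneity.
Hedges g and DL are the classical defaults for two-group expression
meta-analysis; REML-type τ² estimators are deliberately not offered.
Genes with zero pooled SD in a study are excluded from that study only.
Bonferroni correction uses the common-universe size G.

A known numerical consequence of the DL estimator: under exact homogeneity
the truncation τ̂² = max(0, ·) inflates the pooled standard error for the
roughly half of genes where Q exceeds its expectation, so null p-values are
mildly conservative (empirical KS distance from uniform ≈ 0.04–0.05
regardless of gene count, while the fixed-effects and Q p-values are
uniform).  The calibration tests run at the scale where this intrinsic
conservatism still sits inside the 1% KS band; it is a property of the
estimator, not an implementation artifact.

### Prediagnostic arm: per-gene linear mixed models

Each gene's normalized expression is modeled with fixed effects (intercept,
case status coded 1/0 so positive β means upregulated in future cases, two
continuous and three categorical covariates) and independent random
intercepts for the three laboratory batch-date factors (RNA isolation,
hybridization, dye labeling); estimation is REML, and the case coefficient
is tested with a large-sample Wald z-test.  The 39-case matched design is
handled through the fixed covariates, as in conditional-on-covariates
analyses of matched cohort samples; no conditional-logistic machinery.

Because the design matrices are identical for all genes, the REML criterion
is profiled: with γₖ = σₖ²/σ² the covariance is V = σ²(I + Σ γₖZₖZₖ'), and
the Woodbury identity turns each likelihood evaluation into dense algebra
in the (small) total number of batch levels; σ² and β have closed-form
profiles.  Optimization is L-BFGS-B over γ ≥ 0 from two starts with a
Nelder–Mead polish when a line search aborts; ~25 ms per gene at cohort
scale.  The engine is cross-checked in the test suite against statsmodels
MixedLM with the same three crossed variance components.  Variance
components estimated at zero reduce the model continuously: with all
batch factors constant (or γ̂ = 0) the fit is exactly ordinary least
squares.  Aliased fixed columns are dropped with a warning; single-level
batch factors are dropped as unidentifiable.  Degenerate (constant) genes
are excluded from the Bonferroni denominator G_pre; non-converged genes
keep their row with missing p, carry no significance flag, but stay in
G_pre (the universe is "genes attempted", which is conservative and
reproducible).

### Overlap classification

Per common-universe gene, each arm contributes a symbol: '+' if p < 0.05
and the effect (pooled μ, or β_case) is positive, '−' if negative, 'o'
otherwise; the two symbols (clinical first) give one of nine labels.
Concordant genes are tiered: *Bonferroni-concordant* if one arm reached
Bonferroni significance and the other at least nominal significance in the
same direction; *nominal-concordant* if both arms are nominal only.  A
separate roll-up flag records genes Bonferroni-significant in neither arm.
Overlap beyond chance is tested by a Fisher exact (hypergeometric) test on
the 2×2 per-arm significance table within the common universe at both
tiers; the default is one-sided enrichment (the hypothesis is an excess of
joint signals), two-sided available.  Concordance is summarised by the
Spearman correlation of signed −log₁₀ p-values (p = 0 capped at 10⁻³²⁰).

### Downstream analyses

PCA runs on the gene-standardized prediagnostic expression of a gene set
over all samples (cases and controls together); components explaining more
than 5% of variance are retained, at most the first ten examined, with a
fixed sign convention (loading sums positive).  Retained component scores
are regressed, among cases, on time to diagnosis in days together with the
cohort's fixed covariates — the full covariate set, switchable, since a
reduced model is equally defensible.  The component score is the dependent
variable, time the predictor; a negative slope means the component signal
is stronger closer to diagnosis.  Gene-set enrichment of the genes
Bonferroni-significant in either arm uses one-sided Fisher tests per GMT
set intersected with the full common universe (not the union of set
members — simpler and stated), Bonferroni-corrected over the tested sets.
Set composition across the four roll-up categories (similar,
prediagnostic-exclusive, clinical-exclusive, dissimilar) is compared by an
exact conditional 2×K test: all margin-fixed tables are enumerated
(vectorised over compositions of the in-set total) and those no more
probable than the observed table are summed; a seeded Monte Carlo estimate
replaces enumeration above ~2·10⁷ candidate tables.  The driver-gene
lookup annotates an external symbol list with both arms' results and
reports absent genes separately.  The gene–gene correlation structure
(average-linkage ordered Pearson matrix over the similar +
prediagnostic-exclusive genes) is exported descriptively, with no formal
cluster test.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any microarray file format.  Defaults are the study conditions the package
is validated under:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes simulated |
| `studies` | 9 (6 blood, 2 bone marrow, 1 lymph node), arm sizes 14–98 | clinical arm |
| `delta_clinical` | 1.0 | standardized case shift, clinical classes |
| `tau` | 0.2 | SD of per-study effect perturbation (clinical classes only) |
| `missing_gene_fraction` | 0.10 | genes unmeasured per study (forces a real universe intersection) |
| `probe_multiplicity` | {1: .5, 2: .3, 3: .2} | probes per gene; additive offsets, SD 0.5 |
| `n_prediag_cases/controls` | 39 / 438 | cohort scale |
| `followup_range_years` | (1, 17) | case time to diagnosis; Beta(1.3, 2) shape puts the median near 6.9 y |
| `delta_prediag_max` | 1.5 | prediagnostic case shift at diagnosis (t = 0) |
| `progression_model` | linear | g(t) = 1 − t/t_max, or exp(−t/median) |
| `batch_counts`, `batch_sd` | (8, 6, 4), 0.3 | batch levels and random-intercept SD per factor |
| `covariate_effect_sd` | 0.2 | SD of per-gene fixed covariate coefficients |

Each gene belongs to one planted class (shared up/down, one-arm-only
up/down, dissimilar, null; defaults 1%/1%/1%/1%/0.5%/0.5%/0.5%/94.5%).
The prediagnostic case signal is `delta_prediag_max · g(t)` — the
functional form of signal growth before diagnosis is not established, so
both a linear and an exponential g are offered with linear as default,
without any claim that either is the true trajectory.  Covariates are
generic stand-ins (two continuous, three categorical): no formula in the
pipeline depends on what the covariates mean, only on their presence in
the design.  Batch intercepts are drawn per gene and batch level, matching
the per-gene mixed model's assumption.  Probe offsets are additive
constants, so collapsing is exercised with non-identical probes while the
rank transform remains offset-invariant.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: platform-specific intensity distributions,
correlated gene modules (genes are independent given the planted class),
probe-level noise independent of the gene signal, non-ignorable
missingness, population stratification, or any real matching structure.
Recovery results on synthetic data bound what the pipeline can do when its
model is correct; they do not certify performance under model violations.

## Numerical choices

* Ranks: mid-ranks for ties; constant vectors map to all-zero scores with a
  warning (no rank information).
* Zero pooled SD in a study: that study is dropped for that gene only.
* τ̂², γ̂ bounded below at 0; γ bounded above at 10⁴.
* Wald and meta p-values are clipped into (0, 1]; p = 0 is capped at
  10⁻³²⁰ in signed scores with a warning.
* Fisher tests with a degenerate margin return p = 1 by convention.
* Tie tolerance 10⁻⁹ on log-probabilities in the exact 2×K enumeration.
* Sorting: results tables are ordered by p ascending, ties broken by gene
  id, missing p last, so outputs are byte-stable.
* report.json is written with sorted keys and is bit-identical across
  reruns at a fixed seed.

## Validation scales

The test suite validates calibration and recovery at sizes chosen to make
the statistical assertions sharp while keeping the suite fast: null
calibration at 2000 simulated genes (six 50/50 blood studies and the
default cohort), pooled-effect recovery at 6000 genes with 4% shared
signal (≥200 planted shared genes, no masking, so the Monte Carlo error of
the mean is ~0.01), overlap type-I error over 1000 replicate null
universes at the genome-scale universe of 11,904 genes, and progression
recovery over 50 replicate cohorts of 300 genes.  The PC1-vs-time check
orients PC1 by its correlation with case status before asserting a
negative slope, because the loading-sum sign convention is arbitrary with
respect to the case signal when up- and down-regulated genes are mixed.

## Known limitations

* The DL meta p-values are mildly conservative under homogeneity (above).
* The Wald z reference for the case coefficient ignores uncertainty in the
  variance components; with ~480 samples and ≤18 batch levels the effect
  is negligible, but at much smaller cohort sizes a Satterthwaite-type
  correction would be preferable.
* Gene symbols are matched case-sensitively, with no alias resolution.
* The exact 2×K test falls back to Monte Carlo for very large in-set
  totals; the result is flagged.
* No cross-study batch correction is attempted: between-study
  heterogeneity is the meta-analysis' job, and Q/τ² report it.
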