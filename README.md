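# premeta

Do blood gene-expression markers measurable *years before* a chronic
lymphocytic leukemia (CLL) diagnosis overlap with the markers seen in
patients at the clinical stage?  `premeta` implements the analysis framework
for that question as a reusable, tested Python pipeline.  It is aimed at
molecular epidemiologists and computational biologists who want to compare a
prospective (prediagnostic) expression cohort against a heterogeneous
collection of public clinical case–control studies.

## What it computes

1. **Harmonization** — each probe-level study is normalized per gene by a
   rank-based inverse normal transformation (Blom scores,
   Φ⁻¹((r − 3/8)/(n + 1/4))), probes are collapsed to genes by the median
   normalized value, and all studies are restricted to the common gene
   universe.
2. **Clinical arm** — per gene, each study contributes a Hedges-corrected
   standardized mean difference *g* = *J*·(x̄₁ − x̄₀)/*s*ₚ with variance
   *v* = (n₁+n₂)/(n₁n₂) + *g*²/2(n₁+n₂); studies are pooled by
   DerSimonian–Laird random effects
   (τ̂² = max(0, (Q − (S−1))/(Σw − Σw²/Σw))), with Cochran's Q for
   heterogeneity and Bonferroni correction over the universe.
3. **Prediagnostic arm** — per gene, a linear mixed model
   *y* = *X*β + Z₁u₁ + Z₂u₂ + Z₃u₃ + ε (REML) with case status and the
   cohort covariates as fixed effects and random intercepts for the RNA
   isolation, hybridization and dye-labeling dates; Wald z-test on the
   case coefficient.
4. **Overlap** — every common-universe gene gets one of nine labels
   (`++`, `--`, `+o`, `-o`, `o+`, `o-`, `+-`, `-+`, `oo`; first symbol
   clinical, second prediagnostic), tracked at a Bonferroni-concordant and a
   nominal-concordant tier, with one-sided Fisher exact overlap tests and
   the Spearman correlation of signed −log₁₀ p-values.
5. **Downstream** — PCA of the concordant and prediagnostic-exclusive gene
   sets (components retained above 5% explained variance), regression of
   component scores on time to diagnosis among cases, cross-set component
   correlations, gene-set (GMT) enrichment, category-composition tests and
   driver-gene lookup.

A synthetic-data module generates multi-study clinical data and a
prediagnostic cohort (default 39 future cases, 438 controls, 1–17 years of
follow-up) with planted gene classes, so the full pipeline runs and is
validated without any external download.

## Worked example

```bash
premeta simulate --out bundle --seed 1 --n-genes 2000
premeta run --bundle bundle --out results --seed 1
```

prints:

```
universe 774 genes; overlap Fisher p (Bonferroni tier) = 5.4e-13
```

and `results/report.json` contains the full count grid.  On this synthetic
run the clinical arm finds 21 Bonferroni-significant genes (of the 774-gene
common universe) and the prediagnostic arm 69 (of 2000); the planted shared
genes land in the `++`/`--` cells, the overlap Fisher p-values at both
tiers are far below 0.05 (5.4e-13 and 3.1e-10), and PC1 of the `++`/`--`
set falls by 7.5e-4 score units per day of remaining follow-up
(p = 1.2e-4) — the negative time slope expected when the prediagnostic
signal reflects growing early disease.

The same statistics can be derived from a nine-category count grid alone
(no expression data), using the packaged reference counts of the published
genome-wide CLL comparison:

```bash
premeta paper-check
```

```
"replication_percent": 60.3448...,   # (9+6+55)/116 clinical markers replicated
"bonferroni_overlap_fisher_p": 0.00994  # one-sided, table [9,107;360,11428]
```

Library use mirrors statsmodels: build a model object, call `.fit()`, read
the results table.

```python
from premeta import ClinicalMetaAnalysis, PrediagnosticDE, MarkerOverlap

meta = ClinicalMetaAnalysis(gene_studies).fit()          # MetaAnalysisResults
de = PrediagnosticDE(cohort_matrix, pheno).fit()         # PrediagDEResults
overlap = MarkerOverlap(meta, de)
print(overlap.summarize().summary())
```

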