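"""Structure and annotation analyses of the overlap-defined gene sets.

Given the nine-category calls, this module characterises the marker sets:

* PCA of the prediagnostic expression of a gene set (all samples), retaining
  components that explain more than 5% of the variance;
* regression of retained component scores, among future cases, on time to
  diagnosis (days) with the cohort's fixed covariates -- a negative slope
  means the component signal strengthens as diagnosis approaches;
* cross-correlation of retained components between two gene sets (shared
  latent structure);
* gene-set (e.g. KEGG pathway) enrichment of the significant genes by
  one-sided Fisher exact tests with Bonferroni correction over the sets;
* comparison of a set's composition across the four roll-up categories
  (similar, prediagnostic-exclusive, clinical-exclusive, dissimilar) by an
  exact 2 x K test;
* annotation of an external driver-gene list with both arms' results;
* a descriptive gene-gene correlation structure (average-linkage ordering)
  over the similar + prediagnostic-exclusive genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._exact import exact_2xk_test
from .harmonize import GeneMatrix
from .overlap import fisher_overlap_test

__all__ = [
    "PCResult",
    "pca_gene_set",
    "pc_time_association",
    "pc_cross_correlation",
    "geneset_enrichment",
    "category_composition_test",
    "driver_gene_lookup",
    "gene_correlation_structure",
    "ROLLUP_CATEGORIES",
]

VARIANCE_FRACTION_THRESHOLD = 0.05
MAX_COMPONENTS = 10

ROLLUP_CATEGORIES = {
    "similar": ("++", "--"),
    "prediag_exclusive": ("o+", "o-"),
    "clinical_exclusive": ("+o", "-o"),
    "dissimilar": ("+-", "-+"),
}


@dataclass
class PCResult:
    """PCA of one gene set over the prediagnostic samples.

    ``scores`` holds the retained components (samples x PCk, those explaining
    > 5% of total variance, first 10 examined); ``variance_fractions`` covers
    all computed components.  Component signs follow a fixed convention: each
    loading vector sums to a positive value.
    """

    set_id: str
    variance_fractions: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    dropped_genes: list[str]

    @property
    def n_retained(self) -> int:
        return self.scores.shape[1]


def pca_gene_set(
    matrix,
    genes,
    set_id: str = "set",
    threshold: float = VARIANCE_FRACTION_THRESHOLD,
    max_components: int = MAX_COMPONENTS,
) -> PCResult:
    """PCA of the expression of ``genes`` across all samples of ``matrix``.

    Genes are centred and unit-scaled across samples before the singular
    value decomposition of the samples x genes matrix.  Constant genes are
    dropped with a warning; fewer than two usable genes is an error.
    """
    values = matrix.values if isinstance(matrix, GeneMatrix) else matrix
    genes = [g for g in genes if g in values.index]
    sub = values.loc[genes]
    if sub.shape[1] < 3:
        raise ValueError("PCA needs at least three samples")
    sd = sub.std(axis=1, ddof=1)
    dropped = list(sub.index[(sd == 0) | ~np.isfinite(sd)])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant genes from PCA", RuntimeWarning)
        sub = sub.drop(index=dropped)
        sd = sd.drop(index=dropped)
    if sub.shape[0] < 2:
        raise ValueError("PCA needs at least two non-constant genes")
    zs = ((sub.T - sub.mean(axis=1)) / sd).to_numpy()  # samples x genes
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    var_frac = s**2 / (s**2).sum()
    n_examine = min(max_components, len(s))
    retained = [i for i in range(n_examine) if var_frac[i] > threshold]
    # deterministic sign: each loading vector sums positive
    for i in retained:
        if vt[i].sum() < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    cols = [f"PC{i + 1}" for i in retained]
    scores = pd.DataFrame(
        u[:, retained] * s[retained], index=values.columns, columns=cols
    )
    loadings = pd.DataFrame(vt[retained].T, index=sub.index, columns=cols)
    return PCResult(
        set_id=set_id,
        variance_fractions=var_frac,
        scores=scores,
        loadings=loadings,
        dropped_genes=dropped,
    )


def _fixed_covariate_design(pheno: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols, names = [np.ones(len(pheno))], ["intercept"]
    for cov in covariates:
        col = pheno[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).to_numpy())
        else:
            for lev in sorted(col.astype(str).unique())[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def pc_time_association(
    pc: PCResult,
    pheno: pd.DataFrame,
    time_col: str = "time_to_diagnosis_days",
    case_col: str = "case",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Regress each retained component, among cases, on time to diagnosis.

    The component score is the dependent variable; time (days) enters with
    the cohort's fixed covariates (default: every phenotype column other
    than the case flag, the time column and the batch dates).  Returns one
    row per component with slope (score units per day), se, t and p.
    """
    import statsmodels.api as sm

    pheno = pheno.loc[pc.scores.index]
    cases = pheno[pheno[case_col].astype(bool)]
    if len(cases) < 3:
        raise ValueError("time association needs at least three cases")
    if covariates is None:
        skip = {case_col, time_col, "isolation_date", "hybridization_date", "labeling_date"}
        covariates = [c for c in pheno.columns if c not in skip]
    t = cases[time_col].astype(float)
    if t.isna().any():
        raise ValueError("cases with missing time to diagnosis")
    design = np.column_stack(
        [_fixed_covariate_design(cases, covariates), t.to_numpy()]
    )
    rows = []
    for comp in pc.scores.columns:
        y = pc.scores.loc[cases.index, comp].to_numpy()
        if np.allclose(y, y[0]):
            rows.append((comp, 0.0, np.nan, np.nan, np.nan))
            continue
        fit = sm.OLS(y, design).fit()
        rows.append(
            (comp, fit.params[-1], fit.bse[-1], fit.tvalues[-1], fit.pvalues[-1])
        )
    return pd.DataFrame(rows, columns=["component", "slope_per_day", "se", "t", "p"])


def pc_cross_correlation(a: PCResult, b: PCResult) -> pd.DataFrame:
    """Pearson correlations between the retained components of two sets."""
    if not a.scores.index.equals(b.scores.index):
        raise ValueError("PC score tables cover different samples")
    out = np.empty((a.n_retained, b.n_retained))
    for i, ca in enumerate(a.scores.columns):
        for j, cb in enumerate(b.scores.columns):
            out[i, j] = stats.pearsonr(a.scores[ca], b.scores[cb])[0]
    return pd.DataFrame(
        out,
        index=[f"{a.set_id}:{c}" for c in a.scores.columns],
        columns=[f"{b.set_id}:{c}" for c in b.scores.columns],
    )


def geneset_enrichment(
    significant,
    universe,
    gene_sets: dict[str, dict],
    alpha: float = 0.05,
    sided: str = "one",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``significant`` genes per gene set.

    Sets are intersected with the universe; Bonferroni correction runs over
    the sets with a non-empty universe intersection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    significant = set(significant) & universe
    rows = []
    for set_id, entry in gene_sets.items():
        members = set(entry["genes"]) & universe
        if not members:
            continue
        a = len(members & significant)
        b = len(significant) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        p = fisher_overlap_test(a, b, c, d, sided=sided)
        rows.append((set_id, entry.get("description", ""), len(members), a, p))
    table = pd.DataFrame(
        rows, columns=["set_id", "description", "n_universe", "n_significant", "p"]
    )
    n_tested = len(table)
    table["bonferroni_flag"] = table["p"] < (alpha / n_tested if n_tested else 1.0)
    return table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)


def category_composition_test(
    set_genes,
    calls: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict:
    """Compare a set's composition across the four roll-up categories.

    Counts set members against non-members in the similar /
    prediagnostic-exclusive / clinical-exclusive / dissimilar categories
    (consistently non-significant genes are outside all four) and applies an
    exact 2 x K homogeneity test.  With fewer than two non-empty categories
    the test is skipped (``p`` is None).
    """
    members = set(set_genes) & set(calls["gene"])
    in_set = calls["gene"].isin(members)
    inside, outside, used = [], [], []
    for cat, labels in ROLLUP_CATEGORIES.items():
        mask = calls["label"].isin(labels)
        margin = int(mask.sum())
        if margin == 0:
            continue
        used.append(cat)
        inside.append(int((mask & in_set).sum()))
        outside.append(int((mask & ~in_set).sum()))
    counts = {
        cat: {"inside": i, "outside": o} for cat, i, o in zip(used, inside, outside)
    }
    if len(used) < 2 or sum(inside) == 0:
        return {"counts": counts, "categories": used, "p": None, "skipped": True}
    res = exact_2xk_test(inside, outside, rng=rng)
    return {
        "counts": counts,
        "categories": used,
        "p": res["p"],
        "method": res["method"],
        "skipped": False,
    }


def driver_gene_lookup(
    driver_genes,
    calls: pd.DataFrame,
    meta_table: pd.DataFrame,
    prediag_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Annotate an external driver-gene list with both arms' results.

    Absent genes are reported with ``in_universe`` False and excluded from
    the summary denominators.  Returns ``(table, summary)``.
    """
    calls_ix = calls.set_index("gene")
    meta_ix = meta_table.set_index("gene") if "gene" in meta_table.columns else meta_table
    pre_ix = (
        prediag_table.set_index("gene") if "gene" in prediag_table.columns else prediag_table
    )
    rows = []
    for g in driver_genes:
        present = g in calls_ix.index
        row = {
            "gene": g,
            "in_universe": present,
            "label": calls_ix.at[g, "label"] if present else "",
            "tier": calls_ix.at[g, "tier"] if present else "",
            "clinical_p": meta_ix.at[g, "p"] if present and g in meta_ix.index else np.nan,
            "prediag_p": pre_ix.at[g, "p"] if present and g in pre_ix.index else np.nan,
            "clinical_bonferroni": bool(calls_ix.at[g, "clinical_bonferroni"]) if present else False,
            "prediag_bonferroni": bool(calls_ix.at[g, "prediag_bonferroni"]) if present else False,
            "clinical_nominal": bool(calls_ix.at[g, "clinical_nominal"]) if present else False,
            "prediag_nominal": bool(calls_ix.at[g, "prediag_nominal"]) if present else False,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    present = table[table["in_universe"]] if len(table) else table
    summary = {
        "n_listed": int(len(table)),
        "n_present": int(len(present)),
        "n_absent": int(len(table) - len(present)),
        "n_clinical_bonferroni": int(present["clinical_bonferroni"].sum()) if len(present) else 0,
        "n_prediag_bonferroni": int(present["prediag_bonferroni"].sum()) if len(present) else 0,
        "n_clinical_nominal": int(present["clinical_nominal"].sum()) if len(present) else 0,
        "n_prediag_nominal": int(present["prediag_nominal"].sum()) if len(present) else 0,
        "n_concordant": int(present["label"].isin(["++", "--"]).sum()) if len(present) else 0,
    }
    return table, summary


def gene_correlation_structure(matrix, genes) -> tuple[pd.DataFrame, list[str]]:
    """Gene-gene Pearson correlation matrix with average-linkage ordering.

    Descriptive check of whether the similar and prediagnostic-exclusive
    genes form separate correlation blocks; no formal cluster test.
    """
    values = matrix.values if isinstance(matrix, GeneMatrix) else matrix
    genes = [g for g in genes if g in values.index]
    if len(genes) < 3:
        raise ValueError("correlation structure needs at least three genes")
    sub = values.loc[genes]
    corr = np.corrcoef(sub.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(link, squareform(dist, checks=False)))
    ordered = [genes[i] for i in order]
    frame = pd.DataFrame(corr, index=genes, columns=genes).loc[ordered, ordered]
    return frame, ordered
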