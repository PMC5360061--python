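"""Gene-wise random-effects meta-analysis of clinical case--control studies.

Each study contributes, per gene, a standardized mean difference (Hedges g,
case minus control) with its large-sample variance.  Per gene, the study
effects are pooled under a random-effects model with the DerSimonian--Laird
moment estimator of the between-study variance tau^2, and heterogeneity is
assessed with Cochran's Q (chi-square, S-1 df, under homogeneity).

The standardized mean difference d = J * (mean_case - mean_control) / s_pooled
uses the small-sample correction J = 1 - 3 / (4(n1+n2-2) - 1) and variance

    v = (n1+n2) / (n1*n2) + d^2 / (2(n1+n2)).

Pooling: fixed weights w = 1/v give d_FE and Q = sum w (d - d_FE)^2;
tau2 = max(0, (Q - (S-1)) / (sum w - sum w^2 / sum w)); random-effects
weights w* = 1/(v + tau2) give mu, se = (sum w*)^(-1/2), z = mu/se and a
two-sided normal p-value.  When tau2 = 0 the pooled estimate coincides with
the fixed-effects one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import GeneMatrix, intersect_gene_universe

__all__ = [
    "standardized_effect",
    "hedges_correction",
    "dl_random_effects",
    "ClinicalMetaAnalysis",
    "MetaAnalysisResults",
]


def hedges_correction(n1: int, n2: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4(n1+n2-2) - 1)."""
    return 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)


def standardized_effect(case_values, control_values) -> tuple[float, float]:
    """Hedges-corrected standardized mean difference (case - control) and variance.

    Returns ``(d, v)``; raises on groups smaller than two, returns
    ``(nan, nan)`` when the pooled SD is zero (the caller excludes the study
    for that gene).
    """
    x1 = np.asarray(case_values, dtype=float)
    x2 = np.asarray(control_values, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("standardized_effect needs >= 2 values per group")
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        return float("nan"), float("nan")
    d = hedges_correction(n1, n2) * (x1.mean() - x2.mean()) / np.sqrt(s2)
    v = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    return float(d), float(v)


def dl_random_effects(d, v) -> dict:
    """DerSimonian--Laird pooling of one gene's study effects.

    Parameters
    ----------
    d, v : arrays of per-study effects and variances (NaN-free, length >= 2)

    Returns a dict with mu, se, z, p, Q, p_Q, tau2 and S.
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    if d.size < 2:
        raise ValueError("random-effects pooling needs at least two studies")
    w = 1.0 / v
    sw = w.sum()
    d_fe = (w * d).sum() / sw
    q = (w * (d - d_fe) ** 2).sum()
    s = d.size
    c = sw - (w * w).sum() / sw
    tau2 = max(0.0, (q - (s - 1)) / c)
    w_star = 1.0 / (v + tau2)
    mu = (w_star * d).sum() / w_star.sum()
    se = w_star.sum() ** -0.5
    z = mu / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "mu": float(mu),
        "se": float(se),
        "z": float(z),
        "p": float(max(p, np.nextafter(0, 1))),
        "Q": float(q),
        "p_Q": float(stats.chi2.sf(q, s - 1)),
        "tau2": float(tau2),
        "S": int(s),
    }


def _group_stats(values: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-gene mean, ddof-1 variance and count over a column subset, NaN-aware."""
    sub = values[:, cols]
    finite = np.isfinite(sub)
    n = finite.sum(axis=1).astype(float)
    filled = np.where(finite, sub, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        ss = (np.where(finite, sub - mean[:, None], 0.0) ** 2).sum(axis=1)
        var = ss / np.maximum(n - 1, 1)
    var[n < 2] = np.nan
    mean[n < 1] = np.nan
    return mean, var, n


class ClinicalMetaAnalysis:
    """Gene-wise random-effects meta-analysis over harmonized clinical studies.

    Parameters
    ----------
    studies : list of GeneMatrix
        Harmonized (INT + collapsed) gene-level studies with case labels.
    tissue_filter : set of str, optional
        Restrict to studies whose tissue tag is in the set (e.g. ``{"blood"}``
        for the peripheral-blood sensitivity analysis).
    alpha : float
        Family-wise level for the Bonferroni flag (0.05 by default; the
        per-gene threshold is ``alpha / G`` with ``G`` the universe size).

    Examples
    --------
    >>> results = ClinicalMetaAnalysis(studies).fit()
    >>> results.table.head()
    """

    def __init__(
        self,
        studies: list[GeneMatrix],
        tissue_filter: set[str] | None = None,
        alpha: float = 0.05,
    ) -> None:
        if tissue_filter is not None:
            studies = [s for s in studies if s.tissue in tissue_filter]
            if len(studies) < 2:
                raise ValueError(
                    "tissue filter leaves fewer than two studies; "
                    "meta-analysis needs at least two"
                )
        if len(studies) < 2:
            raise ValueError("meta-analysis needs at least two studies")
        for st in studies:
            if st.case is None:
                raise ValueError(f"study {st.study_id!r} has no case/control labels")
            if st.case.sum() == 0 or (~st.case).sum() == 0:
                raise ValueError(
                    f"study {st.study_id!r} lacks cases or controls"
                )
        self.studies = studies
        self.alpha = float(alpha)
        self.universe, self._restricted = intersect_gene_universe(studies)

    def fit(self) -> "MetaAnalysisResults":
        genes = np.array(self.universe)
        g = len(genes)
        s_total = len(self._restricted)
        d_mat = np.full((g, s_total), np.nan)
        v_mat = np.full((g, s_total), np.nan)
        n_zero_sd = 0

        for j, st in enumerate(self._restricted):
            values = st.values.to_numpy(dtype=float)
            case_cols = np.flatnonzero(st.case.to_numpy())
            ctrl_cols = np.flatnonzero(~st.case.to_numpy())
            m1, s1, n1 = _group_stats(values, case_cols)
            m2, s2, n2 = _group_stats(values, ctrl_cols)
            ok = (n1 >= 2) & (n2 >= 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
                jcorr = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
                d = jcorr * (m1 - m2) / np.sqrt(sp2)
                v = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
            zero_sd = ok & ~(sp2 > 0)
            n_zero_sd += int(zero_sd.sum())
            ok &= sp2 > 0
            d_mat[ok, j] = d[ok]
            v_mat[ok, j] = v[ok]

        valid = np.isfinite(d_mat) & np.isfinite(v_mat)
        s_count = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(valid, 1.0 / v_mat, 0.0)
            sw = w.sum(axis=1)
            d0 = np.where(valid, d_mat, 0.0)
            d_fe = (w * d0).sum(axis=1) / sw
            q = (w * np.where(valid, d_mat - d_fe[:, None], 0.0) ** 2).sum(axis=1)
            c = sw - (w**2).sum(axis=1) / sw
            tau2 = np.maximum(0.0, (q - (s_count - 1)) / c)
            w_star = np.where(valid, 1.0 / (v_mat + tau2[:, None]), 0.0)
            mu = (w_star * d0).sum(axis=1) / w_star.sum(axis=1)
            se = w_star.sum(axis=1) ** -0.5
            z = mu / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            p_q = stats.chi2.sf(q, np.maximum(s_count - 1, 1))

        pooled = s_count >= 2
        table = pd.DataFrame(
            {
                "gene": genes,
                "mu": np.where(pooled, mu, np.nan),
                "se": np.where(pooled, se, np.nan),
                "z": np.where(pooled, z, np.nan),
                "p": np.where(pooled, np.clip(p, np.nextafter(0, 1), 1.0), np.nan),
                "Q": np.where(pooled, q, np.nan),
                "p_Q": np.where(pooled, p_q, np.nan),
                "tau2": np.where(pooled, tau2, np.nan),
                "S": s_count,
            }
        )
        g_universe = g
        bonf = self.alpha / g_universe
        table["bonferroni_flag"] = (table["p"] < bonf).fillna(False)
        table["nominal_flag"] = (table["p"] < self.alpha).fillna(False)
        table = table.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
        return MetaAnalysisResults(
            table=table,
            universe=list(genes),
            alpha=self.alpha,
            n_studies=s_total,
            n_zero_sd_excluded=n_zero_sd,
            tissues=[st.tissue for st in self._restricted],
        )


@dataclass
class MetaAnalysisResults:
    """Results of :class:`ClinicalMetaAnalysis.fit`.

    ``table`` holds one row per universe gene (sorted by p, ties by gene id)
    with columns gene, mu, se, z, p, Q, p_Q, tau2, S, bonferroni_flag,
    nominal_flag.
    """

    table: pd.DataFrame
    universe: list[str]
    alpha: float
    n_studies: int
    n_zero_sd_excluded: int
    tissues: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_genes

    @property
    def n_bonferroni(self) -> int:
        return int(self.table["bonferroni_flag"].sum())

    @property
    def n_nominal(self) -> int:
        return int(self.table["nominal_flag"].sum())

    def heterogeneity_summary(self) -> dict:
        """Fraction of genes with Bonferroni-significant Cochran Q."""
        p_q = self.table["p_Q"].dropna()
        frac = float((p_q < self.bonferroni_threshold).mean()) if len(p_q) else float("nan")
        return {
            "n_genes": self.n_genes,
            "frac_bonferroni_Q": frac,
            "frac_nominal_Q": float((p_q < self.alpha).mean()) if len(p_q) else float("nan"),
        }

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("gene")

    def summary(self) -> str:
        het = self.heterogeneity_summary()
        lines = [
            "Gene-wise random-effects meta-analysis (DerSimonian-Laird)",
            f"  studies pooled:       {self.n_studies} ({', '.join(self.tissues)})",
            f"  common gene universe: {self.n_genes}",
            f"  Bonferroni threshold: {self.bonferroni_threshold:.3e}",
            f"  Bonferroni-significant genes: {self.n_bonferroni}",
            f"  nominal-significant genes:    {self.n_nominal}",
            f"  Bonferroni-significant heterogeneity (Q): "
            f"{100 * het['frac_bonferroni_Q']:.1f}% of genes",
            f"  zero-SD study/gene exclusions: {self.n_zero_sd_excluded}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
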