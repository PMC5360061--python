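"""Harmonization of heterogeneous probe-level expression studies.

Public expression studies arrive on different platforms, preprocessed in
different (sometimes undocumented) ways.  Before any cross-study pooling the
pipeline puts every study on a common footing:

1. rank-based inverse normal transformation (INT, Blom offset 3/8) of each
   probe's values across the samples of that study, which removes
   platform-specific scale and distribution shape;
2. collapsing probes to genes by the median normalized value, so each gene is
   represented once per study;
3. restriction of all studies to the genes measured in every study (the
   common gene universe).

The INT is applied per gene/probe across samples (the default), because the
downstream standardized effects compare case and control distributions
gene-wise.  A per-sample mode is available for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GeneMatrix",
    "rank_inverse_normal",
    "rank_inverse_normal_frame",
    "collapse_probes_to_genes",
    "intersect_gene_universe",
    "harmonize_study",
]

#: Blom offset used in the rank transformation: Phi^-1((r - 3/8) / (n + 1/4)).
BLOM_OFFSET = 0.375


@dataclass
class GeneMatrix:
    """Gene-level expression for one study.

    Parameters
    ----------
    values : DataFrame
        Genes (rows) by samples (columns); normal scores after harmonization.
    case : Series of bool, indexed by sample id
        True for case samples.  May be omitted for matrices that are only
        used descriptively.
    tissue : str
        Sampling tissue tag (``blood``, ``bone_marrow``, ``lymph_node``).
    study_id : str
    """

    values: pd.DataFrame
    case: pd.Series | None = None
    tissue: str = "blood"
    study_id: str = "study"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        if self.case is not None:
            self.case = self.case.reindex(self.values.columns)
            if self.case.isna().any():
                missing = list(self.case.index[self.case.isna()])
                raise ValueError(
                    f"samples without case/control label in study "
                    f"{self.study_id!r}: {missing[:5]}"
                )
            self.case = self.case.astype(bool)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, genes) -> "GeneMatrix":
        return GeneMatrix(
            self.values.loc[list(genes)],
            case=self.case,
            tissue=self.tissue,
            study_id=self.study_id,
        )


def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Map a numeric vector to normal scores via its (mid-)ranks.

    Output is ``Phi^-1((r - offset) / (n + 1 - 2*offset))`` with ``r`` the
    mid-rank among the non-missing entries; ties receive equal scores and
    missing values stay missing.  A constant vector has no rank information:
    it maps to all zeros, with a warning.

    Parameters
    ----------
    values : array-like of float, NaN = missing
    offset : float
        Rank offset; 3/8 (Blom) by default, giving the denominator n + 1/4.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("rank_inverse_normal requires >= 2 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        warnings.warn(
            "constant vector passed to rank_inverse_normal; returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        out[mask] = 0.0
        return out
    r = stats.rankdata(obs, method="average")
    out[mask] = special.ndtri((r - offset) / (n + 1.0 - 2.0 * offset))
    return out


def rank_inverse_normal_frame(
    frame: pd.DataFrame, axis: str = "gene", offset: float = BLOM_OFFSET
) -> pd.DataFrame:
    """Apply the INT row-wise (``axis='gene'``) or column-wise (``'sample'``).

    Vectorised over rows: mid-ranks are computed per row with missing entries
    excluded; constant rows become all-zero (without a per-row warning --
    callers that care use :func:`rank_inverse_normal` directly).
    """
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    x = frame.to_numpy(dtype=float)
    if axis == "sample":
        x = x.T
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    n_obs = finite.sum(axis=1)
    if np.any(n_obs < 2):
        raise ValueError("every vector needs >= 2 non-missing values for the INT")
    if finite.all():
        r = stats.rankdata(x, method="average", axis=1)
        denom = x.shape[1] + 1.0 - 2.0 * offset
        out = special.ndtri((r - offset) / denom)
        const = (x == x[:, :1]).all(axis=1)
        out[const] = 0.0
    else:
        for i in range(x.shape[0]):
            row = x[i]
            m = finite[i]
            obs = row[m]
            if np.all(obs == obs[0]):
                out[i, m] = 0.0
                continue
            r = stats.rankdata(obs, method="average")
            out[i, m] = special.ndtri((r - offset) / (n_obs[i] + 1.0 - 2.0 * offset))
    if axis == "sample":
        out = out.T
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def collapse_probes_to_genes(
    matrix: pd.DataFrame, probe_map: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Collapse a probes-by-samples matrix to genes by the per-gene median.

    Parameters
    ----------
    matrix : DataFrame, probes x samples
    probe_map : Series mapping probe id -> gene symbol (many-to-one)

    Returns
    -------
    (gene_matrix, n_unmapped) : the genes-by-samples median matrix and the
    number of matrix probes that had no gene assignment (dropped).

    Missing cells are excluded from each median; a gene/sample cell whose
    probes are all missing stays missing.
    """
    probe_map = pd.Series(probe_map)
    mapped = matrix.index.intersection(probe_map.index)
    n_unmapped = matrix.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the probe map")
    genes = probe_map.loc[mapped]
    collapsed = matrix.loc[mapped].groupby(genes.to_numpy()).median()
    collapsed.index.name = "gene"
    return collapsed, int(n_unmapped)


def intersect_gene_universe(studies: list[GeneMatrix]) -> tuple[list[str], list[GeneMatrix]]:
    """Restrict studies to the sorted intersection of their gene sets.

    Only genes measured in every study enter the meta-analysis; the returned
    matrices share one row order.
    """
    if len(studies) < 2:
        raise ValueError("gene-universe intersection needs at least two studies")
    universe = set(studies[0].genes)
    for st in studies[1:]:
        universe &= set(st.genes)
    if not universe:
        raise ValueError("empty gene universe: no gene is measured in all studies")
    ordered = sorted(universe)
    return ordered, [st.restrict(ordered) for st in studies]


def harmonize_study(
    probe_matrix: pd.DataFrame,
    probe_map: pd.Series,
    case: pd.Series | None = None,
    tissue: str = "blood",
    study_id: str = "study",
    int_axis: str = "gene",
) -> GeneMatrix:
    """INT-normalise then median-collapse one probe-level study.

    Normalisation precedes collapsing, so probe-level distributional
    differences are removed before probes of a gene are summarised.
    """
    normed = rank_inverse_normal_frame(probe_matrix, axis=int_axis)
    collapsed, _ = collapse_probes_to_genes(normed, probe_map)
    return GeneMatrix(collapsed, case=case, tissue=tissue, study_id=study_id)
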