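"""Nine-category overlap classification of clinical vs. prediagnostic markers.

Every gene of the common universe gets a two-symbol label: the first symbol
summarises the clinical meta-analysis ('+' nominally significant and
upregulated, '-' nominally significant and downregulated, 'o' otherwise),
the second the prediagnostic mixed model.  The nine labels are
++, --, +o, -o, o+, o-, +-, -+ and oo.

Concordant genes ('++' or '--') are tracked at two significance tiers:

* ``bonferroni`` -- Bonferroni-corrected significance in at least one arm and
  nominal significance in the other (the "differentially expressed in both"
  rule);
* ``nominal`` -- nominal significance in both arms only.

Whether a gene reached Bonferroni in neither arm is kept as a separate
roll-up flag (``null_rollup``), orthogonal to the direction label.

Overlap beyond chance is tested with a one-sided Fisher exact
(hypergeometric) test on the 2x2 table of per-arm significance within the
common universe, at both tiers, and concordance of the two arms is
quantified by the Spearman correlation of signed -log10 p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import MetaAnalysisResults
from .prediag import PrediagDEResults

__all__ = [
    "LABELS",
    "classify_gene",
    "build_category_counts",
    "fisher_overlap_test",
    "signed_log10p",
    "signed_p_concordance",
    "MarkerOverlap",
    "OverlapSummary",
]

LABELS = ("++", "--", "+o", "-o", "o+", "o-", "+-", "-+", "oo")

_P_CAP = 320.0  # -log10 floor for p == 0


def _arm_symbol(p: float, effect: float, alpha: float) -> str:
    if not np.isfinite(p) or p >= alpha:
        return "o"
    if effect > 0:
        return "+"
    if effect < 0:
        return "-"
    warnings.warn(
        "significant arm with zero effect; direction undefined, using 'o'",
        RuntimeWarning,
        stacklevel=3,
    )
    return "o"


def classify_gene(
    clinical_p: float,
    clinical_effect: float,
    prediag_p: float,
    prediag_effect: float,
    alpha_bonf_clin: float,
    alpha_bonf_pre: float,
    alpha: float = 0.05,
) -> dict:
    """Label one gene from its two arms' p-values and effect directions.

    Returns a dict with ``label`` (one of the nine), ``tier`` (``bonferroni``,
    ``nominal`` or ``none``), ``bonferroni_side`` (``none``/``clinical``/
    ``prediag``/``both``) and ``null_rollup`` (True when neither arm reached
    Bonferroni significance).
    """
    sym_c = _arm_symbol(clinical_p, clinical_effect, alpha)
    sym_p = _arm_symbol(prediag_p, prediag_effect, alpha)
    label = sym_c + sym_p

    bonf_c = np.isfinite(clinical_p) and clinical_p < alpha_bonf_clin
    bonf_p = np.isfinite(prediag_p) and prediag_p < alpha_bonf_pre
    side = {
        (False, False): "none",
        (True, False): "clinical",
        (False, True): "prediag",
        (True, True): "both",
    }[(bool(bonf_c), bool(bonf_p))]

    concordant = label in ("++", "--")
    if concordant and (bonf_c or bonf_p):
        tier = "bonferroni"
    elif concordant:
        tier = "nominal"
    else:
        tier = "none"
    return {
        "label": label,
        "tier": tier,
        "bonferroni_side": side,
        "null_rollup": not (bonf_c or bonf_p),
    }


def signed_log10p(p: float, effect_sign: float) -> float:
    """Signed significance score: sign(effect) * (-log10 p); p = 1 maps to 0."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        warnings.warn("p == 0 capped at 1e-320 for the signed score", RuntimeWarning)
        mag = _P_CAP
    else:
        mag = -np.log10(p)
    return float(np.sign(effect_sign) * mag)


def signed_p_concordance(clinical_scores, prediag_scores) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) of paired signed scores."""
    a = np.asarray(clinical_scores, dtype=float)
    b = np.asarray(prediag_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired over the same universe")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def fisher_overlap_test(a: int, b: int, c: int, d: int, sided: str = "one") -> float:
    """Fisher exact test on the 2x2 significance-overlap table.

    ``a`` = significant in both arms, ``b`` = clinical only, ``c`` =
    prediagnostic only, ``d`` = neither.  One-sided = upper hypergeometric
    tail P(X >= a); degenerate margins give p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    if sided == "one":
        return float(stats.hypergeom.sf(a - 1, n, row1, col1))
    if sided == "two":
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError("sided must be 'one' or 'two'")


def build_category_counts(calls: pd.DataFrame) -> dict:
    """Count the (label, tier, Bonferroni-side) cells of a calls table.

    ``calls`` is the per-gene table produced by :class:`MarkerOverlap`
    (columns label, tier, bonferroni_side).  Returns label counts, tier
    counts, the concordant-direction grid and the directional Venn layers.
    """
    label_counts = {lab: int((calls["label"] == lab).sum()) for lab in LABELS}
    tier_counts = {
        t: int((calls["tier"] == t).sum()) for t in ("bonferroni", "nominal", "none")
    }
    grid: dict[str, dict[str, int]] = {}
    for direction, lab in (("up", "++"), ("down", "--")):
        sub = calls[calls["label"] == lab]
        grid[direction] = {
            "bonferroni_both": int((sub["bonferroni_side"] == "both").sum()),
            "prediag_bonf_clinical_nominal": int((sub["bonferroni_side"] == "prediag").sum()),
            "clinical_bonf_prediag_nominal": int((sub["bonferroni_side"] == "clinical").sum()),
            "nominal_both": int((sub["bonferroni_side"] == "none").sum()),
        }
    venn_layers = {
        direction: {
            "bonferroni": sum(
                grid[direction][k]
                for k in ("bonferroni_both", "prediag_bonf_clinical_nominal", "clinical_bonf_prediag_nominal")
            ),
            "nominal": grid[direction]["nominal_both"],
        }
        for direction in ("up", "down")
    }
    return {
        "label_counts": label_counts,
        "tier_counts": tier_counts,
        "concordant_grid": grid,
        "venn_layers": venn_layers,
    }


@dataclass
class OverlapSummary:
    """All overlap counts and statistics for one universe."""

    universe_size: int
    label_counts: dict
    tier_counts: dict
    concordant_grid: dict
    venn_layers: dict
    clinical_bonferroni: int
    prediag_bonferroni: int
    clinical_nominal: int
    prediag_nominal: int
    fisher: dict
    spearman_rho: float
    spearman_p: float

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "label_counts": self.label_counts,
            "tier_counts": self.tier_counts,
            "concordant_grid": self.concordant_grid,
            "venn_layers": self.venn_layers,
            "clinical_bonferroni": self.clinical_bonferroni,
            "prediag_bonferroni": self.prediag_bonferroni,
            "clinical_nominal": self.clinical_nominal,
            "prediag_nominal": self.prediag_nominal,
            "fisher": self.fisher,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
        }

    def summary(self) -> str:
        lines = [
            "Clinical vs. prediagnostic marker overlap",
            f"  common universe: {self.universe_size} genes",
            f"  Bonferroni-significant: clinical {self.clinical_bonferroni}, "
            f"prediagnostic {self.prediag_bonferroni}",
            "  labels: "
            + "  ".join(f"{lab}:{self.label_counts[lab]}" for lab in LABELS),
            f"  concordant tiers: Bonferroni {self.tier_counts['bonferroni']}, "
            f"nominal {self.tier_counts['nominal']}",
            f"  overlap Fisher p (Bonferroni tier): {self.fisher['bonferroni']['p']:.3g}",
            f"  overlap Fisher p (nominal tier):    {self.fisher['nominal']['p']:.3g}",
            f"  Spearman rho of signed -log10 p:    {self.spearman_rho:.3f}",
        ]
        return "\n".join(lines)


class MarkerOverlap:
    """Classify a common universe of genes from the two arms' results.

    Parameters
    ----------
    meta : MetaAnalysisResults
    prediag : PrediagDEResults
    alpha : float
        Nominal level (0.05).
    sided : 'one' or 'two'
        Sidedness of the overlap Fisher tests (one-sided enrichment default).

    The universe is the set of genes present in both results tables.  The
    per-arm Bonferroni thresholds are carried over from the two analyses
    (each arm's own universe size is the denominator).
    """

    def __init__(
        self,
        meta: MetaAnalysisResults,
        prediag: PrediagDEResults,
        alpha: float = 0.05,
        sided: str = "one",
    ) -> None:
        self.meta = meta
        self.prediag = prediag
        self.alpha = float(alpha)
        self.sided = sided
        m = meta.indexed()
        d = prediag.indexed()
        common = m.index.intersection(d.index).sort_values()
        if len(common) == 0:
            raise ValueError("no gene shared between the two arms")
        self._m = m.loc[common]
        self._d = d.loc[common]
        self.universe = list(common)
        self.calls = self._classify()

    def _classify(self) -> pd.DataFrame:
        ab_c = self.meta.bonferroni_threshold
        ab_p = self.prediag.bonferroni_threshold
        cp = self._m["p"].to_numpy()
        ce = self._m["mu"].to_numpy()
        pp = self._d["p"].to_numpy()
        pe = self._d["beta_case"].to_numpy()

        def symbols(p, eff):
            sig = np.isfinite(p) & (p < self.alpha)
            out = np.where(sig & (eff > 0), "+", np.where(sig & (eff < 0), "-", "o"))
            if np.any(sig & (eff == 0)):
                warnings.warn(
                    "significant arm with zero effect; direction undefined, using 'o'",
                    RuntimeWarning,
                )
            return out

        sym_c = symbols(cp, ce)
        sym_p = symbols(pp, pe)
        label = np.char.add(sym_c.astype("U1"), sym_p.astype("U1"))
        bonf_c = np.isfinite(cp) & (cp < ab_c)
        bonf_p = np.isfinite(pp) & (pp < ab_p)
        side = np.select(
            [bonf_c & bonf_p, bonf_c, bonf_p],
            ["both", "clinical", "prediag"],
            default="none",
        )
        concordant = (label == "++") | (label == "--")
        tier = np.select(
            [concordant & (bonf_c | bonf_p), concordant],
            ["bonferroni", "nominal"],
            default="none",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score_c = np.sign(ce) * -np.log10(np.clip(cp, 1e-320, 1.0))
            score_p = np.sign(pe) * -np.log10(np.clip(pp, 1e-320, 1.0))
        return pd.DataFrame(
            {
                "gene": self.universe,
                "label": label,
                "tier": tier,
                "bonferroni_side": side,
                "null_rollup": ~(bonf_c | bonf_p),
                "clinical_nominal": np.isfinite(cp) & (cp < self.alpha),
                "prediag_nominal": np.isfinite(pp) & (pp < self.alpha),
                "clinical_bonferroni": bonf_c,
                "prediag_bonferroni": bonf_p,
                "signed_log10p_clinical": score_c,
                "signed_log10p_prediag": score_p,
            }
        )

    def summarize(self) -> OverlapSummary:
        calls = self.calls
        counts = build_category_counts(calls)
        fisher = {}
        for tier_name, col in (
            ("bonferroni", "bonferroni"),
            ("nominal", "nominal"),
        ):
            sc = calls[f"clinical_{col}"].to_numpy()
            sp = calls[f"prediag_{col}"].to_numpy()
            a = int((sc & sp).sum())
            b = int((sc & ~sp).sum())
            c = int((~sc & sp).sum())
            d = int((~sc & ~sp).sum())
            fisher[tier_name] = {
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": fisher_overlap_test(a, b, c, d, sided=self.sided),
            }
        finite = np.isfinite(calls["signed_log10p_clinical"]) & np.isfinite(
            calls["signed_log10p_prediag"]
        )
        rho, rho_p = signed_p_concordance(
            calls.loc[finite, "signed_log10p_clinical"],
            calls.loc[finite, "signed_log10p_prediag"],
        )
        return OverlapSummary(
            universe_size=len(calls),
            label_counts=counts["label_counts"],
            tier_counts=counts["tier_counts"],
            concordant_grid=counts["concordant_grid"],
            venn_layers=counts["venn_layers"],
            clinical_bonferroni=int(calls["clinical_bonferroni"].sum()),
            prediag_bonferroni=int(calls["prediag_bonferroni"].sum()),
            clinical_nominal=int(calls["clinical_nominal"].sum()),
            prediag_nominal=int(calls["prediag_nominal"].sum()),
            fisher=fisher,
            spearman_rho=rho,
            spearman_p=rho_p,
        )

    def genes_with_labels(self, labels) -> list[str]:
        """Universe genes whose direction label is in ``labels``."""
        mask = self.calls["label"].isin(set(labels))
        return self.calls.loc[mask, "gene"].tolist()

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
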