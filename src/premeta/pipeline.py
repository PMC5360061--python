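"""End-to-end orchestration and the machine-readable report.

``run_pipeline`` sequences harmonize -> clinical meta-analysis ->
prediagnostic mixed models -> overlap classification -> downstream analyses
over a fixture bundle on disk, writing every stage's TSV plus a
``report.json`` that contains only numbers reproducible by calling the
underlying module operations directly.

``check_reference_counts`` recomputes, from a nine-category count grid alone
(the packaged fixture carries the published counts of the motivating
genome-wide CLL comparison), the clinical-arm replication percentage, the
Bonferroni-tier overlap contingency table with its Fisher p-value, and the
directional Venn layers -- no expression data required.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream, io
from .harmonize import GeneMatrix, harmonize_study
from .meta import ClinicalMetaAnalysis, MetaAnalysisResults
from .overlap import MarkerOverlap, fisher_overlap_test
from .prediag import PrediagnosticDE
from .simulate import read_fixture_bundle

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_reference_counts",
    "check_reference_counts",
    "validate_report",
    "REPORT_REQUIRED_KEYS",
]

log = logging.getLogger("premeta")

REPORT_REQUIRED_KEYS = {
    "clinical_meta": dict,
    "prediagnostic": dict,
    "overlap": dict,
    "downstream": dict,
    "settings": dict,
}


@dataclass
class PipelineConfig:
    """Paths and switches for one pipeline run (YAML-serialisable)."""

    bundle_dir: str
    out_dir: str
    gene_sets: str | None = None
    driver_list: str | None = None
    alpha: float = 0.05
    tissue_filter: list[str] | None = None
    sided: str = "one"
    int_axis: str = "gene"
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.int_axis not in ("gene", "sample"):
            raise ValueError("int_axis must be 'gene' or 'sample'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def harmonize_bundle(studies, cohort, int_axis: str = "gene"):
    """Harmonize raw study bundles and the cohort into GeneMatrix objects."""
    gene_studies = []
    for st in studies:
        case = st.pheno["group"].astype(str) == "case"
        gene_studies.append(
            harmonize_study(
                st.probe_matrix,
                st.probe_map,
                case=case,
                tissue=st.tissue,
                study_id=st.study_id,
                int_axis=int_axis,
            )
        )
    cohort_case = cohort.pheno["case"].astype(int) == 1
    cohort_matrix = harmonize_study(
        cohort.probe_matrix,
        cohort.probe_map,
        case=cohort_case,
        tissue="blood",
        study_id="prediag",
        int_axis=int_axis,
    )
    return gene_studies, cohort_matrix


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full comparison pipeline; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading bundle from %s", config.bundle_dir)
    studies, cohort, truth = read_fixture_bundle(config.bundle_dir)

    log.info("harmonizing %d studies + cohort (INT axis=%s)", len(studies), config.int_axis)
    gene_studies, cohort_matrix = harmonize_bundle(studies, cohort, config.int_axis)

    tissue_filter = set(config.tissue_filter) if config.tissue_filter else None
    log.info("clinical meta-analysis (tissue filter: %s)", tissue_filter or "none")
    meta_model = ClinicalMetaAnalysis(gene_studies, tissue_filter=tissue_filter, alpha=config.alpha)
    meta_res = meta_model.fit()
    meta_res.to_tsv(out / "clinical_meta.tsv")

    log.info("prediagnostic mixed models on %d genes", cohort_matrix.values.shape[0])
    de_model = PrediagnosticDE(cohort_matrix, cohort.pheno, alpha=config.alpha)
    de_res = de_model.fit()
    de_res.to_tsv(out / "prediag_de.tsv")

    log.info("overlap classification")
    ov = MarkerOverlap(meta_res, de_res, alpha=config.alpha, sided=config.sided)
    ov.to_tsv(out / "overlap_calls.tsv")
    ov_summary = ov.summarize()

    ds_report = _run_downstream(config, out, cohort, cohort_matrix, ov, meta_res, de_res)

    report = {
        "settings": {
            "bundle_dir": str(config.bundle_dir),
            "alpha": config.alpha,
            "tissue_filter": sorted(tissue_filter) if tissue_filter else None,
            "sided": config.sided,
            "int_axis": config.int_axis,
            "seed": config.seed,
            "n_studies_pooled": meta_res.n_studies,
        },
        "clinical_meta": {
            "universe_size": meta_res.n_genes,
            "bonferroni_threshold": meta_res.bonferroni_threshold,
            "n_bonferroni": meta_res.n_bonferroni,
            "n_nominal": meta_res.n_nominal,
            "heterogeneity": meta_res.heterogeneity_summary(),
        },
        "prediagnostic": {
            "g_pre": de_res.g_pre,
            "bonferroni_threshold": de_res.bonferroni_threshold,
            "n_bonferroni": de_res.n_bonferroni,
            "n_nominal": de_res.n_nominal,
            "n_samples": de_res.n_samples,
        },
        "overlap": ov_summary.to_dict(),
        "downstream": ds_report,
    }
    validate_report(report)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    log.info("report written to %s", out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _run_downstream(config, out, cohort, cohort_matrix, ov, meta_res, de_res) -> dict:
    rng = np.random.default_rng(config.seed)
    report: dict = {"pca": {}, "pc_time": {}, "pc_cross_correlation": None}

    pcs = {}
    for set_name, labels in (("similar", ("++", "--")), ("prediag_exclusive", ("o+", "o-"))):
        genes = ov.genes_with_labels(labels)
        if len(genes) < 2:
            log.info("set %s has %d genes; PCA skipped", set_name, len(genes))
            report["pca"][set_name] = {"n_genes": len(genes), "skipped": True}
            continue
        pc = downstream.pca_gene_set(cohort_matrix, genes, set_id=set_name)
        pcs[set_name] = pc
        case_mask = (cohort.pheno["case"].astype(int) == 1).to_numpy()
        # +1 when the component is elevated in future cases, -1 otherwise;
        # lets consumers orient the sign-convention-bound scores
        case_dir = {
            comp: int(np.sign(
                pc.scores.loc[case_mask, comp].mean()
                - pc.scores.loc[~case_mask, comp].mean()
            ) or 1)
            for comp in pc.scores.columns
        }
        assoc = downstream.pc_time_association(pc, cohort.pheno)
        assoc.to_csv(out / f"pc_time_{set_name}.tsv", sep="\t", index=False)
        report["pca"][set_name] = {
            "n_genes": len(genes) - len(pc.dropped_genes),
            "skipped": False,
            "variance_fractions": [round(float(v), 6) for v in pc.variance_fractions[:10]],
            "n_retained": pc.n_retained,
        }
        report["pc_time"][set_name] = [
            {
                "component": r.component,
                "slope_per_day": None if pd.isna(r.slope_per_day) else float(r.slope_per_day),
                "p": None if pd.isna(r.p) else float(r.p),
                "case_direction": case_dir[r.component],
            }
            for r in assoc.itertuples()
        ]
    if len(pcs) == 2 and all(pc.n_retained for pc in pcs.values()):
        cc = downstream.pc_cross_correlation(pcs["similar"], pcs["prediag_exclusive"])
        cc.to_csv(out / "pc_cross_correlation.tsv", sep="\t")
        report["pc_cross_correlation"] = {
            "max_abs": float(np.abs(cc.to_numpy()).max()),
            "pc1_pc1": float(cc.iloc[0, 0]),
        }

    report["enrichment"] = None
    report["composition"] = None
    if config.gene_sets:
        sets = io.read_gmt(config.gene_sets)
        significant = ov.calls.loc[
            ov.calls["clinical_bonferroni"] | ov.calls["prediag_bonferroni"], "gene"
        ].tolist()
        enr = downstream.geneset_enrichment(
            significant, ov.universe, sets, alpha=config.alpha, sided=config.sided
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "n_sets_tested": int(len(enr)),
            "n_enriched": int(enr["bonferroni_flag"].sum()),
            "top": enr.head(5)[["set_id", "p"]].to_dict("records"),
        }
        comp = {}
        for set_id in enr.loc[enr["bonferroni_flag"], "set_id"]:
            res = downstream.category_composition_test(
                sets[set_id]["genes"], ov.calls, rng=rng
            )
            comp[set_id] = {"p": res["p"], "counts": res["counts"], "skipped": res["skipped"]}
        report["composition"] = comp

    report["drivers"] = None
    if config.driver_list:
        drivers = io.read_driver_list(config.driver_list)
        table, summary = downstream.driver_gene_lookup(
            drivers, ov.calls, meta_res.table, de_res.table
        )
        table.to_csv(out / "drivers.tsv", sep="\t", index=False)
        report["drivers"] = summary

    if config.make_plots:
        _make_plots(out, cohort, ov, pcs)
    return report


def _make_plots(out, cohort, ov, pcs) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        ov.calls["signed_log10p_clinical"],
        ov.calls["signed_log10p_prediag"],
        s=4,
        alpha=0.4,
    )
    ax.set_xlabel("clinical signed -log10 p")
    ax.set_ylabel("prediagnostic signed -log10 p")
    fig.savefig(out / "signed_p_scatter.png", dpi=120)
    plt.close(fig)

    if "similar" in pcs and pcs["similar"].n_retained:
        pc = pcs["similar"]
        case = cohort.pheno["case"].astype(bool)
        t = cohort.pheno["time_to_diagnosis_days"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(t[case], pc.scores.loc[case.index[case], "PC1"], c="red", s=12, label="cases")
        ax.set_xlabel("time to diagnosis (days)")
        ax.set_ylabel("PC1 score")
        ax.legend()
        fig.savefig(out / "pc1_vs_time.png", dpi=120)
        plt.close(fig)


def validate_report(report: dict) -> None:
    """Check the report against the bundled key/type schema."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing required section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} has wrong type")
    for key in ("universe_size", "n_bonferroni", "n_nominal"):
        if key not in report["clinical_meta"]:
            raise ValueError(f"clinical_meta section missing {key!r}")
    for key in ("g_pre", "n_bonferroni", "n_nominal"):
        if key not in report["prediagnostic"]:
            raise ValueError(f"prediagnostic section missing {key!r}")
    for key in ("label_counts", "fisher", "spearman_rho"):
        if key not in report["overlap"]:
            raise ValueError(f"overlap section missing {key!r}")


def load_reference_counts(path=None) -> dict:
    """Load a nine-category counts file (default: the packaged reference)."""
    if path is None:
        ref = resources.files("premeta.data").joinpath("reference_counts.json")
        return json.loads(ref.read_text(encoding="utf-8"))
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def check_reference_counts(counts: dict | None = None, sided: str = "one") -> dict:
    """Derive the headline overlap statistics from a count grid alone.

    Computes the clinical-arm replication percentage (share of clinical
    Bonferroni genes that reached at least nominal significance with the
    same direction prediagnostically), the Bonferroni-tier 2x2 overlap table
    with its Fisher p-value, and the directional Venn layers.
    """
    if counts is None:
        counts = load_reference_counts()
    grid = counts["concordant_grid"]
    universe = int(counts["universe"])
    clin_total = int(counts["clinical_bonferroni_total"])

    flat = [universe, clin_total, int(counts["prediag_exclusive"]), int(counts["clinical_exclusive"])]
    flat += [int(v) for d in grid.values() for v in d.values()]
    flat += [int(v) for v in counts.get("dissimilar", {}).values()]
    if any(v < 0 for v in flat):
        raise ValueError("counts must be non-negative")
    if any(v > universe for v in flat[1:]):
        raise ValueError("a count exceeds the stated universe size")
    if clin_total == 0:
        raise ValueError("clinical Bonferroni total must be positive")

    bonf_both = sum(grid[d]["bonferroni_both"] for d in ("up", "down"))
    clin_bonf_replicated = bonf_both + sum(
        grid[d]["clinical_bonf_prediag_nominal"] for d in ("up", "down")
    )
    replication_percent = 100.0 * clin_bonf_replicated / clin_total

    prediag_in_universe = (
        bonf_both
        + sum(grid[d]["prediag_bonf_clinical_nominal"] for d in ("up", "down"))
        + int(counts["prediag_exclusive"])
    )
    a = bonf_both
    b = clin_total - a
    c = prediag_in_universe - a
    d = universe - a - b - c
    if min(b, c, d) < 0:
        raise ValueError("inconsistent counts: negative derived contingency cell")
    fisher_p = fisher_overlap_test(a, b, c, d, sided=sided)

    venn_layers = {
        direction: {
            "bonferroni": grid[direction]["bonferroni_both"]
            + grid[direction]["prediag_bonf_clinical_nominal"]
            + grid[direction]["clinical_bonf_prediag_nominal"],
            "nominal": grid[direction]["nominal_both"],
        }
        for direction in ("up", "down")
    }
    return {
        "replication_percent": replication_percent,
        "n_clinical_bonferroni_replicated": clin_bonf_replicated,
        "clinical_bonferroni_total": clin_total,
        "prediag_bonferroni_in_universe": prediag_in_universe,
        "bonferroni_overlap_table": {"a": a, "b": b, "c": c, "d": d},
        "bonferroni_overlap_fisher_p": fisher_p,
        "venn_layers": venn_layers,
    }
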