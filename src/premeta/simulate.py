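"""Synthetic multi-study clinical data and a prediagnostic cohort.

The generator emulates the statistical structure the pipeline assumes, with
gene-level ground truth:

* a set of clinical case--control expression studies on different platforms
  (1-3 probes per gene with additive probe offsets, study-specific probe
  identifiers, a fraction of genes unmeasured per study) and tissues, whose
  case signal is a standardized shift perturbed per study by between-study
  heterogeneity of SD ``tau``;
* a prediagnostic cohort (default 39 future cases, 438 controls, matching the
  cohort scale the pipeline is built for) whose case signal grows as
  diagnosis approaches, confounded by fixed covariates and three batch-date
  random intercepts (RNA isolation, hybridization, dye labeling).

Every gene belongs to one planted class -- shared signal, one-arm-only
signal, opposite-direction signal, or null -- so recovery and calibration of
the full pipeline can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io

__all__ = [
    "PLANTED_CLASSES",
    "StudyDesign",
    "SimulationConfig",
    "StudyBundle",
    "CohortBundle",
    "progression_weight",
    "assign_ground_truth",
    "simulate_clinical_studies",
    "simulate_prediag_cohort",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

PLANTED_CLASSES = (
    "shared_up",
    "shared_down",
    "prediag_only_up",
    "prediag_only_down",
    "clinical_only_up",
    "clinical_only_down",
    "dissimilar",
    "null",
)

#: classes with a clinical-arm signal component (between-study heterogeneity
#: of SD ``tau`` applies to these genes' per-study effects)
_CLINICAL_CLASSES = frozenset(
    {"shared_up", "shared_down", "clinical_only_up", "clinical_only_down", "dissimilar"}
)
_PREDIAG_CLASSES = frozenset(
    {"shared_up", "shared_down", "prediag_only_up", "prediag_only_down", "dissimilar"}
)

_TISSUES = ("blood", "bone_marrow", "lymph_node")

#: SD of the additive per-probe offsets (exercises median collapsing)
PROBE_OFFSET_SD = 0.5

DAYS_PER_YEAR = 365.25

# Follow-up times are drawn as t_min + range * Beta(a, b); these shape
# parameters put the median near 6.9 years on the default 1-17 year interval,
# the design median of the cohort being emulated.
_FOLLOWUP_BETA = (1.3, 2.0)


@dataclass(frozen=True)
class StudyDesign:
    n_cases: int
    n_controls: int
    tissue: str = "blood"


def _default_studies() -> tuple[StudyDesign, ...]:
    # Nine studies: six peripheral blood, two bone marrow, one lymph node,
    # with arm sizes spanning the range typical of public CLL series.
    return (
        StudyDesign(50, 30, "blood"),
        StudyDesign(40, 40, "blood"),
        StudyDesign(98, 60, "blood"),
        StudyDesign(24, 24, "blood"),
        StudyDesign(33, 33, "blood"),
        StudyDesign(60, 41, "blood"),
        StudyDesign(26, 15, "bone_marrow"),
        StudyDesign(30, 21, "bone_marrow"),
        StudyDesign(21, 14, "lymph_node"),
    )


def _default_fractions() -> dict[str, float]:
    return {
        "shared_up": 0.010,
        "shared_down": 0.010,
        "prediag_only_up": 0.010,
        "prediag_only_down": 0.010,
        "clinical_only_up": 0.005,
        "clinical_only_down": 0.005,
        "dissimilar": 0.005,
        "null": 0.945,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic clinical studies and cohort.

    Effects are in standardized (within-group SD) units.  ``tau`` is the SD
    of the per-study perturbation of the clinical effect (between-study
    heterogeneity).  The prediagnostic case effect at time-to-diagnosis ``t``
    is ``delta_prediag_max * g(t)`` with ``g`` the progression weight.
    """

    n_genes: int = 2000
    studies: tuple[StudyDesign, ...] = field(default_factory=_default_studies)
    probe_multiplicity: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    delta_clinical: float = 1.0
    delta_prediag_max: float = 1.5
    tau: float = 0.2
    missing_gene_fraction: float = 0.10
    n_prediag_cases: int = 39
    n_prediag_controls: int = 438
    followup_range_years: tuple[float, float] = (1.0, 17.0)
    progression_model: str = "linear"
    batch_counts: tuple[int, int, int] = (8, 6, 4)
    batch_sd: float = 0.3
    covariate_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.studies:
            raise ValueError("at least one clinical study is required")
        for i, st in enumerate(self.studies):
            if st.tissue not in _TISSUES:
                raise ValueError(f"unknown tissue {st.tissue!r} in study {i}")
            if st.n_cases <= 0 or st.n_controls <= 0:
                raise ValueError(
                    f"study {i} ({st.tissue}) needs positive case and control counts"
                )
        mult = self.probe_multiplicity
        if set(mult) - {1, 2, 3} or abs(sum(mult.values()) - 1.0) > 1e-9:
            raise ValueError("probe_multiplicity must be a distribution over {1,2,3}")
        unknown = set(self.class_fractions) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if self.delta_clinical < 0 or self.delta_prediag_max < 0 or self.tau < 0:
            raise ValueError("effect magnitudes and tau must be >= 0")
        if not 0 <= self.missing_gene_fraction < 1:
            raise ValueError("missing_gene_fraction must lie in [0, 1)")
        if self.n_prediag_cases <= 0 or self.n_prediag_controls <= 0:
            raise ValueError("prediagnostic case and control counts must be positive")
        lo, hi = self.followup_range_years
        if not lo < hi:
            raise ValueError("degenerate follow-up interval: min must be < max")
        if lo < 0:
            raise ValueError("follow-up times must be non-negative")
        if self.progression_model not in ("linear", "exponential"):
            raise ValueError("progression_model must be 'linear' or 'exponential'")
        if len(self.batch_counts) != 3 or any(b < 1 for b in self.batch_counts):
            raise ValueError("batch_counts must be three positive integers")
        if self.batch_sd < 0 or self.covariate_effect_sd < 0:
            raise ValueError("batch_sd and covariate_effect_sd must be >= 0")

    @property
    def median_followup_years(self) -> float:
        """Median of the follow-up time distribution (closed form)."""
        lo, hi = self.followup_range_years
        a, b = _FOLLOWUP_BETA
        return lo + (hi - lo) * stats.beta.ppf(0.5, a, b)


@dataclass
class StudyBundle:
    """Raw outputs for one simulated clinical study."""

    study_id: str
    probe_matrix: pd.DataFrame
    probe_map: pd.Series
    pheno: pd.DataFrame
    tissue: str


@dataclass
class CohortBundle:
    """Raw outputs for the simulated prediagnostic cohort."""

    probe_matrix: pd.DataFrame
    probe_map: pd.Series
    pheno: pd.DataFrame


def progression_weight(t_years, config: SimulationConfig) -> np.ndarray:
    """Signal weight g(t) at time-to-diagnosis ``t`` (years before diagnosis).

    ``linear``: g(t) = 1 - t / t_max (zero at the far end of follow-up);
    ``exponential``: g(t) = exp(-t / median follow-up).  Both decrease in t
    and equal 1 at diagnosis (t = 0).
    """
    t = np.asarray(t_years, dtype=float)
    if config.progression_model == "linear":
        t_max = config.followup_range_years[1]
        return 1.0 - t / t_max
    return np.exp(-t / config.median_followup_years)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"GENE{i:05d}" for i in range(n)])


def assign_ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted class and true effects per gene.

    Deterministic given the config seed, and shared by both simulators so the
    two arms agree on which gene carries which signal.  Dissimilar genes get
    a random orientation (clinical up / prediagnostic down or vice versa).
    """
    rng = _rng(config, 0)
    genes = _gene_ids(config.n_genes)
    classes = np.array(PLANTED_CLASSES)
    probs = np.array([config.class_fractions.get(c, 0.0) for c in classes])
    planted = rng.choice(classes, size=config.n_genes, p=probs)

    clin = np.zeros(config.n_genes)
    pre = np.zeros(config.n_genes)
    dc, dp = config.delta_clinical, config.delta_prediag_max
    clin[planted == "shared_up"] = dc
    clin[planted == "shared_down"] = -dc
    clin[planted == "clinical_only_up"] = dc
    clin[planted == "clinical_only_down"] = -dc
    pre[planted == "shared_up"] = dp
    pre[planted == "shared_down"] = -dp
    pre[planted == "prediag_only_up"] = dp
    pre[planted == "prediag_only_down"] = -dp
    dis = planted == "dissimilar"
    orient = np.where(rng.random(int(dis.sum())) < 0.5, 1.0, -1.0)
    clin[dis] = dc * orient
    pre[dis] = -dp * orient

    return pd.DataFrame(
        {
            "gene": genes,
            "planted_class": planted,
            "true_clinical_effect": clin,
            "true_prediag_effect_at_diagnosis": pre,
        }
    ).set_index("gene")


def _expand_probes(
    gene_values: np.ndarray,
    genes: np.ndarray,
    rng: np.random.Generator,
    config: SimulationConfig,
    prefix: str,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Turn a genes-by-samples array into a probe-level matrix.

    Each gene is measured by 1-3 probes; a probe's row is the gene's row plus
    an additive probe-specific offset, mimicking platform probe effects that
    median collapsing (after normalization) must absorb.
    """
    counts = np.array(sorted(config.probe_multiplicity))
    probs = np.array([config.probe_multiplicity[c] for c in counts], dtype=float)
    mult = rng.choice(counts, size=len(genes), p=probs)
    probe_gene_idx = np.repeat(np.arange(len(genes)), mult)
    offsets = rng.normal(0.0, PROBE_OFFSET_SD, size=len(probe_gene_idx))
    values = gene_values[probe_gene_idx] + offsets[:, None]
    probe_ids = np.array([f"{prefix}P{i:06d}" for i in range(len(probe_gene_idx))])
    probe_map = pd.Series(genes[probe_gene_idx], index=probe_ids, name="gene")
    probe_map.index.name = "probe"
    return values, probe_map, probe_ids


def simulate_clinical_studies(
    config: SimulationConfig,
) -> tuple[list[StudyBundle], pd.DataFrame]:
    """Generate the clinical arm: one probe-level bundle per study.

    Per study, gene-level values are ``baseline + effect * case + noise``
    with ``effect = true_clinical_effect + Normal(0, tau^2)`` for genes of a
    clinical planted class, unit-variance noise, and a random
    ``missing_gene_fraction`` of genes left unmeasured to force a nontrivial
    common universe.
    """
    truth = assign_ground_truth(config)
    rng = _rng(config, 1)
    genes = truth.index.to_numpy()
    clin_eff = truth["true_clinical_effect"].to_numpy()
    is_clin = truth["planted_class"].isin(_CLINICAL_CLASSES).to_numpy()

    bundles: list[StudyBundle] = []
    for s, design in enumerate(config.studies):
        study_id = f"study{s + 1:02d}"
        if design.n_cases <= 0 or design.n_controls <= 0:
            raise ValueError(f"{study_id}: zero cases or controls")
        n = design.n_cases + design.n_controls
        case_flag = np.r_[np.ones(design.n_cases), np.zeros(design.n_controls)]

        n_missing = int(round(config.missing_gene_fraction * config.n_genes))
        missing = rng.choice(config.n_genes, size=n_missing, replace=False)
        keep = np.setdiff1d(np.arange(config.n_genes), missing)

        effect = np.where(is_clin, clin_eff + rng.normal(0.0, config.tau, config.n_genes), 0.0)
        baseline = rng.normal(0.0, 1.0, size=config.n_genes)
        values = (
            baseline[keep, None]
            + effect[keep, None] * case_flag[None, :]
            + rng.normal(0.0, 1.0, size=(len(keep), n))
        )

        probe_values, probe_map, probe_ids = _expand_probes(
            values, genes[keep], rng, config, prefix=f"{study_id}_"
        )
        sample_ids = [
            f"{study_id}_case{i + 1:03d}" for i in range(design.n_cases)
        ] + [f"{study_id}_ctrl{i + 1:03d}" for i in range(design.n_controls)]
        matrix = pd.DataFrame(probe_values, index=probe_ids, columns=sample_ids)
        matrix.index.name = "probe"
        pheno = pd.DataFrame(
            {
                "group": np.where(case_flag == 1, "case", "control"),
                "tissue": design.tissue,
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        bundles.append(StudyBundle(study_id, matrix, probe_map, pheno, design.tissue))
    return bundles, truth.reset_index()


def simulate_prediag_cohort(
    config: SimulationConfig,
) -> tuple[CohortBundle, pd.DataFrame]:
    """Generate the prediagnostic cohort with planted progression.

    The phenotype table carries the case flag, time to diagnosis in days
    (cases only), two continuous and three categorical covariates (generic
    stand-ins for the epidemiological adjustment set) and three batch-date
    factors.  The case effect for prediagnostic-class genes is
    ``delta_prediag_max * g(t)``; batch intercepts ``Normal(0, batch_sd^2)``
    and covariate effects ``Normal(0, covariate_effect_sd^2)`` apply to every
    gene.
    """
    lo, hi = config.followup_range_years
    if not lo < hi:
        raise ValueError("degenerate follow-up interval: min must be < max")
    truth = assign_ground_truth(config)
    rng = _rng(config, 2)
    genes = truth.index.to_numpy()
    pre_eff = truth["true_prediag_effect_at_diagnosis"].to_numpy()

    n_case, n_ctrl = config.n_prediag_cases, config.n_prediag_controls
    n = n_case + n_ctrl
    case_flag = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
    sample_ids = [f"PD_case{i + 1:03d}" for i in range(n_case)] + [
        f"PD_ctrl{i + 1:03d}" for i in range(n_ctrl)
    ]

    a, b = _FOLLOWUP_BETA
    t_years = lo + (hi - lo) * rng.beta(a, b, size=n_case)
    t_days = np.full(n, np.nan)
    t_days[:n_case] = t_years * DAYS_PER_YEAR

    # generic covariate stand-ins (continuous x2, categorical x3)
    age = rng.normal(55.0, 8.0, size=n)
    bmi = rng.normal(26.0, 4.0, size=n)
    sex = rng.choice(["F", "M"], size=n)
    country = rng.choice(["IT", "SE"], size=n)
    phase = rng.choice(["A", "B"], size=n)
    iso, hyb, lab = (
        rng.integers(0, config.batch_counts[k], size=n) for k in range(3)
    )

    g_weight = np.zeros(n)
    g_weight[:n_case] = progression_weight(t_years, config)
    signal = pre_eff[:, None] * g_weight[None, :]

    cov_cols = [
        (age - age.mean()) / age.std(),
        (bmi - bmi.mean()) / bmi.std(),
        (sex == "M").astype(float),
        (country == "SE").astype(float),
        (phase == "B").astype(float),
    ]
    cov_mat = np.column_stack(cov_cols)  # n x 5
    cov_beta = rng.normal(0.0, config.covariate_effect_sd, size=(config.n_genes, 5))

    batch_part = np.zeros((config.n_genes, n))
    for levels, assign in zip(config.batch_counts, (iso, hyb, lab)):
        intercepts = rng.normal(0.0, config.batch_sd, size=(config.n_genes, levels))
        batch_part += intercepts[:, assign]

    baseline = rng.normal(0.0, 1.0, size=config.n_genes)
    values = (
        baseline[:, None]
        + signal
        + cov_beta @ cov_mat.T
        + batch_part
        + rng.normal(0.0, 1.0, size=(config.n_genes, n))
    )

    probe_values, probe_map, probe_ids = _expand_probes(
        values, genes, rng, config, prefix="PD_"
    )
    matrix = pd.DataFrame(probe_values, index=probe_ids, columns=sample_ids)
    matrix.index.name = "probe"
    pheno = pd.DataFrame(
        {
            "case": case_flag.astype(int),
            "time_to_diagnosis_days": t_days,
            "age": age,
            "bmi": bmi,
            "sex": sex,
            "country": country,
            "phase": phase,
            "isolation_date": [f"iso{v + 1:02d}" for v in iso],
            "hybridization_date": [f"hyb{v + 1:02d}" for v in hyb],
            "labeling_date": [f"lab{v + 1:02d}" for v in lab],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return CohortBundle(matrix, probe_map, pheno), truth.reset_index()


def write_fixture_bundle(
    path,
    studies: list[StudyBundle],
    cohort: CohortBundle,
    truth: pd.DataFrame,
) -> dict:
    """Write TSV matrices, maps, phenotypes, the truth table and a manifest.

    Returns the manifest dict; everything round-trips losslessly through
    :func:`read_fixture_bundle`.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"studies": [], "cohort": {}, "truth": "truth.tsv", "files": []}

    def _record(name: str) -> str:
        manifest["files"].append(name)
        return str(root / name)

    for st in studies:
        entry = {
            "study_id": st.study_id,
            "tissue": st.tissue,
            "matrix": f"{st.study_id}_matrix.tsv",
            "probe_map": f"{st.study_id}_probes.tsv",
            "pheno": f"{st.study_id}_pheno.tsv",
        }
        io.write_matrix(st.probe_matrix, _record(entry["matrix"]))
        io.write_probe_map(st.probe_map, _record(entry["probe_map"]))
        io.write_pheno(st.pheno, _record(entry["pheno"]))
        manifest["studies"].append(entry)

    manifest["cohort"] = {
        "matrix": "prediag_matrix.tsv",
        "probe_map": "prediag_probes.tsv",
        "pheno": "prediag_pheno.tsv",
    }
    io.write_matrix(cohort.probe_matrix, _record("prediag_matrix.tsv"))
    io.write_probe_map(cohort.probe_map, _record("prediag_probes.tsv"))
    io.write_pheno(cohort.pheno, _record("prediag_pheno.tsv"))

    truth.set_index("gene").to_csv(root / "truth.tsv", sep="\t", float_format="%.10g")
    manifest["files"].append("truth.tsv")
    io.write_manifest(manifest, root / "manifest.json")
    manifest["files"].append("manifest.json")
    return manifest


def read_fixture_bundle(path) -> tuple[list[StudyBundle], CohortBundle, pd.DataFrame]:
    root = Path(path)
    manifest = io.read_manifest(root / "manifest.json")
    studies = []
    for entry in manifest["studies"]:
        studies.append(
            StudyBundle(
                study_id=entry["study_id"],
                probe_matrix=io.read_matrix(root / entry["matrix"]),
                probe_map=io.read_probe_map(root / entry["probe_map"]),
                pheno=io.read_pheno(root / entry["pheno"]),
                tissue=entry["tissue"],
            )
        )
    c = manifest["cohort"]
    cohort = CohortBundle(
        probe_matrix=io.read_matrix(root / c["matrix"]),
        probe_map=io.read_probe_map(root / c["probe_map"]),
        pheno=io.read_pheno(root / c["pheno"]),
    )
    truth = pd.read_csv(root / "truth.tsv", sep="\t").fillna({"planted_class": "null"})
    return studies, cohort, truth
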