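"""Shared fixtures: small synthetic bundles generated at test time."""

import numpy as np
import pytest

from premeta.harmonize import harmonize_study
from premeta.simulate import (
    SimulationConfig,
    StudyDesign,
    simulate_clinical_studies,
    simulate_prediag_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """Compact study conditions for fast unit tests."""
    return SimulationConfig(
        n_genes=60,
        studies=(
            StudyDesign(20, 20, "blood"),
            StudyDesign(25, 15, "blood"),
            StudyDesign(18, 22, "bone_marrow"),
        ),
        n_prediag_cases=30,
        n_prediag_controls=120,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_clinical(small_config):
    return simulate_clinical_studies(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_prediag_cohort(small_config)


@pytest.fixture(scope="session")
def small_cohort_matrix(small_cohort):
    cohort, _ = small_cohort
    return harmonize_study(
        cohort.probe_matrix,
        cohort.probe_map,
        case=cohort.pheno["case"] == 1,
        study_id="prediag",
    )


@pytest.fixture(scope="session")
def small_gene_studies(small_clinical):
    studies, _ = small_clinical
    return [
        harmonize_study(
            s.probe_matrix,
            s.probe_map,
            case=s.pheno["group"] == "case",
            tissue=s.tissue,
            study_id=s.study_id,
        )
        for s in studies
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
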