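"""Synthetic-data generator: determinism, planted truth, progression, IO."""

import numpy as np
import pandas as pd
import pytest

from premeta.simulate import (
    PLANTED_CLASSES,
    SimulationConfig,
    StudyDesign,
    assign_ground_truth,
    progression_weight,
    read_fixture_bundle,
    simulate_clinical_studies,
    simulate_prediag_cohort,
    write_fixture_bundle,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="class_fractions"):
            SimulationConfig(class_fractions={"null": 0.5, "shared_up": 0.4})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown planted classes"):
            SimulationConfig(class_fractions={"null": 0.5, "bogus": 0.5})

    def test_negative_effects_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(delta_clinical=-1.0)

    def test_degenerate_followup_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SimulationConfig(followup_range_years=(5.0, 5.0))

    def test_zero_arm_study_rejected(self):
        with pytest.raises(ValueError, match="study 0"):
            SimulationConfig(studies=(StudyDesign(0, 10, "blood"),))

    def test_probe_multiplicity_distribution(self):
        with pytest.raises(ValueError, match="probe_multiplicity"):
            SimulationConfig(probe_multiplicity={1: 0.5, 4: 0.5})


class TestGroundTruth:
    def test_every_gene_exactly_once(self, small_config):
        truth = assign_ground_truth(small_config)
        assert len(truth) == small_config.n_genes
        assert truth.index.is_unique

    def test_null_genes_have_zero_effects(self, small_config):
        truth = assign_ground_truth(small_config)
        nulls = truth[truth["planted_class"] == "null"]
        assert (nulls["true_clinical_effect"] == 0).all()
        assert (nulls["true_prediag_effect_at_diagnosis"] == 0).all()

    def test_classes_within_catalogue(self, small_config):
        truth = assign_ground_truth(small_config)
        assert set(truth["planted_class"]) <= set(PLANTED_CLASSES)

    def test_dissimilar_genes_have_opposite_signs(self):
        config = SimulationConfig(
            n_genes=200, class_fractions={"dissimilar": 0.5, "null": 0.5}, seed=5
        )
        truth = assign_ground_truth(config)
        dis = truth[truth["planted_class"] == "dissimilar"]
        assert (
            np.sign(dis["true_clinical_effect"])
            == -np.sign(dis["true_prediag_effect_at_diagnosis"])
        ).all()

    def test_shared_across_both_simulators(self, small_config):
        _, t1 = simulate_clinical_studies(small_config)
        _, t2 = simulate_prediag_cohort(small_config)
        pd.testing.assert_frame_equal(t1, t2)


class TestProgression:
    def test_weight_is_one_at_diagnosis(self):
        for model in ("linear", "exponential"):
            cfg = SimulationConfig(progression_model=model)
            assert progression_weight(0.0, cfg) == pytest.approx(1.0)

    def test_linear_weight_zero_at_followup_end(self):
        cfg = SimulationConfig(progression_model="linear")
        assert progression_weight(cfg.followup_range_years[1], cfg) == pytest.approx(0.0)

    @pytest.mark.parametrize("model", ["linear", "exponential"])
    def test_weight_decreases_with_time(self, model):
        cfg = SimulationConfig(progression_model=model)
        t = np.linspace(*cfg.followup_range_years, 50)
        w = progression_weight(t, cfg)
        assert np.all(np.diff(w) < 0)

    def test_median_followup_matches_design(self):
        cfg = SimulationConfig()
        assert cfg.median_followup_years == pytest.approx(6.9, abs=0.3)


class TestClinicalSimulation:
    def test_deterministic_given_seed(self, small_config, small_clinical):
        studies2, truth2 = simulate_clinical_studies(small_config)
        studies1, truth1 = small_clinical
        pd.testing.assert_frame_equal(truth1, truth2)
        for a, b in zip(studies1, studies2):
            pd.testing.assert_frame_equal(a.probe_matrix, b.probe_matrix)
            pd.testing.assert_series_equal(a.probe_map, b.probe_map)

    def test_study_shapes_and_labels(self, small_config, small_clinical):
        studies, _ = small_clinical
        assert len(studies) == len(small_config.studies)
        for st, design in zip(studies, small_config.studies):
            assert st.probe_matrix.shape[1] == design.n_cases + design.n_controls
            assert (st.pheno["group"] == "case").sum() == design.n_cases
            assert st.tissue == design.tissue

    def test_missing_gene_fraction_applied(self, small_config, small_clinical):
        studies, _ = small_clinical
        expected = small_config.n_genes - round(
            small_config.missing_gene_fraction * small_config.n_genes
        )
        for st in studies:
            assert st.probe_map.nunique() == expected

    def test_case_shift_matches_planted_effect(self):
        """Two-sample mean difference on the raw gene matrix recovers the
        planted clinical effect (tau = 0, direct t-test oracle)."""
        cfg = SimulationConfig(
            n_genes=400,
            studies=(StudyDesign(80, 80, "blood"),),
            class_fractions={"shared_up": 0.5, "null": 0.5},
            delta_clinical=1.0,
            tau=0.0,
            missing_gene_fraction=0.0,
            probe_multiplicity={1: 1.0},
            seed=9,
        )
        studies, truth = simulate_clinical_studies(cfg)
        st = studies[0]
        gene_of = st.probe_map.to_dict()
        case = (st.pheno["group"] == "case").to_numpy()
        diffs = (
            st.probe_matrix.loc[:, case].mean(axis=1)
            - st.probe_matrix.loc[:, ~case].mean(axis=1)
        )
        diffs.index = [gene_of[p] for p in diffs.index]
        planted = truth.set_index("gene")
        up = planted[planted["planted_class"] == "shared_up"].index
        null = planted[planted["planted_class"] == "null"].index
        assert diffs.loc[up].mean() == pytest.approx(1.0, abs=0.05)
        assert diffs.loc[null].mean() == pytest.approx(0.0, abs=0.05)


class TestPrediagSimulation:
    def test_pheno_structure(self, small_config, small_cohort):
        cohort, _ = small_cohort
        ph = cohort.pheno
        assert (ph["case"].isin([0, 1])).all()
        cases = ph[ph["case"] == 1]
        controls = ph[ph["case"] == 0]
        assert len(cases) == small_config.n_prediag_cases
        assert cases["time_to_diagnosis_days"].notna().all()
        assert (cases["time_to_diagnosis_days"] > 0).all()
        assert controls["time_to_diagnosis_days"].isna().all()
        lo, hi = small_config.followup_range_years
        t_years = cases["time_to_diagnosis_days"] / 365.25
        assert ((t_years >= lo) & (t_years <= hi)).all()

    def test_no_signal_without_effect(self):
        """delta_prediag_max = 0, no batch/covariate structure: per-gene
        t-tests are null (direct oracle on the generated matrix)."""
        cfg = SimulationConfig(
            n_genes=300,
            delta_prediag_max=0.0,
            delta_clinical=0.0,
            batch_sd=0.0,
            covariate_effect_sd=0.0,
            n_prediag_cases=40,
            n_prediag_controls=60,
            probe_multiplicity={1: 1.0},
            seed=21,
        )
        cohort, _ = simulate_prediag_cohort(cfg)
        from scipy import stats

        case = (cohort.pheno["case"] == 1).to_numpy()
        x = cohort.probe_matrix.to_numpy()
        p = stats.ttest_ind(x[:, case], x[:, ~case], axis=1).pvalue
        assert (p < 0.05).mean() < 0.12  # ~5% expected, generous binomial slack

    def test_ttest_recovers_planted_effect(self):
        """With batch/covariate effects off, the raw case-control difference
        equals the planted effect times the mean progression weight."""
        cfg = SimulationConfig(
            n_genes=500,
            class_fractions={"prediag_only_up": 0.4, "null": 0.6},
            delta_prediag_max=1.0,
            batch_sd=0.0,
            covariate_effect_sd=0.0,
            n_prediag_cases=60,
            n_prediag_controls=60,
            probe_multiplicity={1: 1.0},
            seed=13,
        )
        cohort, truth = simulate_prediag_cohort(cfg)
        from premeta.simulate import progression_weight

        ph = cohort.pheno
        case = (ph["case"] == 1).to_numpy()
        t_years = ph.loc[case, "time_to_diagnosis_days"].to_numpy() / 365.25
        mean_weight = progression_weight(t_years, cfg).mean()
        gene_of = cohort.probe_map.to_dict()
        diffs = (
            cohort.probe_matrix.loc[:, case].mean(axis=1)
            - cohort.probe_matrix.loc[:, ~case].mean(axis=1)
        )
        diffs.index = [gene_of[p] for p in diffs.index]
        up = truth.set_index("gene").query("planted_class == 'prediag_only_up'").index
        assert diffs.loc[up].mean() == pytest.approx(mean_weight, abs=0.05)


class TestFixtureBundle:
    def test_round_trip(self, tmp_path, small_clinical, small_cohort):
        studies, truth = small_clinical
        cohort, _ = small_cohort
        manifest = write_fixture_bundle(tmp_path / "bundle", studies, cohort, truth)
        studies2, cohort2, truth2 = read_fixture_bundle(tmp_path / "bundle")
        np.testing.assert_allclose(
            studies[0].probe_matrix.to_numpy(), studies2[0].probe_matrix.to_numpy()
        )
        np.testing.assert_allclose(
            cohort.probe_matrix.to_numpy(), cohort2.probe_matrix.to_numpy()
        )
        assert list(truth2["gene"]) == list(truth["gene"])

    def test_manifest_lists_every_file(self, tmp_path, small_clinical, small_cohort):
        studies, truth = small_clinical
        cohort, _ = small_cohort
        manifest = write_fixture_bundle(tmp_path / "b", studies, cohort, truth)
        on_disk = {p.name for p in (tmp_path / "b").iterdir()}
        assert set(manifest["files"]) == on_disk

    def test_truth_row_count(self, tmp_path, small_config, small_clinical, small_cohort):
        studies, truth = small_clinical
        cohort, _ = small_cohort
        write_fixture_bundle(tmp_path / "b", studies, cohort, truth)
        _, _, truth2 = read_fixture_bundle(tmp_path / "b")
        assert len(truth2) == small_config.n_genes
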