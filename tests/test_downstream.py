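"""PCA of marker sets, time association, enrichment and composition tests."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from premeta._exact import exact_2xk_test
from premeta.downstream import (
    category_composition_test,
    driver_gene_lookup,
    gene_correlation_structure,
    geneset_enrichment,
    pc_cross_correlation,
    pc_time_association,
    pca_gene_set,
)


def exact_2xk_enumeration(row1, row2):
    """Brute-force oracle: iterate all margin-fixed tables with exact fractions."""
    m = [a + b for a, b in zip(row1, row2)]
    r_tot = sum(row1)
    n = sum(m)
    denom = comb(n, r_tot)
    obs = Fraction(int(np.prod([comb(mi, ri) for mi, ri in zip(m, row1)])), denom)
    total = Fraction(0)
    for cells in product(*(range(mi + 1) for mi in m[:-1])):
        last = r_tot - sum(cells)
        if last < 0 or last > m[-1]:
            continue
        table = list(cells) + [last]
        prob = Fraction(int(np.prod([comb(mi, ri) for mi, ri in zip(m, table)])), denom)
        if prob <= obs:
            total += prob
    return float(total)


class TestPCA:
    def _matrix(self, rng, n_genes=10, n_samples=40):
        return pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_two_perfectly_correlated_genes(self, rng):
        base = rng.normal(size=30)
        matrix = pd.DataFrame(
            [base, 2 * base + 1], index=["G0", "G1"], columns=[f"s{i}" for i in range(30)]
        )
        pc = pca_gene_set(matrix, ["G0", "G1"])
        assert pc.variance_fractions[0] == pytest.approx(1.0)
        assert pc.n_retained == 1

    def test_variance_fractions_sum_to_one(self, rng):
        pc = pca_gene_set(self._matrix(rng), [f"G{i}" for i in range(10)])
        assert pc.variance_fractions.sum() == pytest.approx(1.0)
        assert (pc.variance_fractions >= 0).all()

    def test_retention_rule_over_five_percent(self, rng):
        pc = pca_gene_set(self._matrix(rng), [f"G{i}" for i in range(10)])
        retained = (pc.variance_fractions[:10] > 0.05).sum()
        assert pc.n_retained == retained

    def test_sign_convention_loadings_sum_positive(self, rng):
        pc = pca_gene_set(self._matrix(rng), [f"G{i}" for i in range(10)])
        assert (pc.loadings.sum(axis=0) > 0).all()

    def test_gene_reordering_invariance(self, rng):
        matrix = self._matrix(rng)
        genes = [f"G{i}" for i in range(10)]
        pc1 = pca_gene_set(matrix, genes)
        pc2 = pca_gene_set(matrix, genes[::-1])
        pd.testing.assert_frame_equal(pc1.scores, pc2.scores)

    def test_planted_latent_factor_dominates(self, rng):
        factor = rng.normal(size=60)
        genes = {f"G{i}": 0.9 * factor + rng.normal(scale=0.9, size=60) for i in range(8)}
        matrix = pd.DataFrame(genes).T
        matrix.columns = [f"s{i}" for i in range(60)]
        pc = pca_gene_set(matrix, list(genes))
        assert pc.variance_fractions[0] > pc.variance_fractions[1:].max()

    def test_constant_gene_dropped_with_warning(self, rng):
        matrix = self._matrix(rng, n_genes=4)
        matrix.loc["G0"] = 1.0
        with pytest.warns(RuntimeWarning, match="constant genes"):
            pc = pca_gene_set(matrix, ["G0", "G1", "G2", "G3"])
        assert pc.dropped_genes == ["G0"]

    def test_too_few_genes_error(self, rng):
        with pytest.raises(ValueError):
            pca_gene_set(self._matrix(rng, n_genes=2), ["G0"])


class TestTimeAssociation:
    def test_constant_score_gives_zero_slope(self, small_cohort, small_cohort_matrix):
        cohort, _ = small_cohort
        pc = pca_gene_set(small_cohort_matrix, list(small_cohort_matrix.genes[:5]))
        pc.scores["PC1"] = 1.0
        assoc = pc_time_association(pc, cohort.pheno).set_index("component")
        assert assoc.at["PC1", "slope_per_day"] == 0.0

    def test_null_scores_not_significant(self, small_cohort, small_cohort_matrix, rng):
        cohort, _ = small_cohort
        pc = pca_gene_set(small_cohort_matrix, list(small_cohort_matrix.genes[:5]))
        hits = 0
        for _ in range(40):
            for col in pc.scores.columns:
                pc.scores[col] = rng.normal(size=len(pc.scores))
            assoc = pc_time_association(pc, cohort.pheno)
            hits += int((assoc["p"] < 0.05).any())
        # per-component level 5%; any-of-k inflates, stay below a loose cap
        assert hits / 40 < 0.45

    def test_too_few_cases_error(self, small_cohort, small_cohort_matrix):
        cohort, _ = small_cohort
        pc = pca_gene_set(small_cohort_matrix, list(small_cohort_matrix.genes[:4]))
        pheno = cohort.pheno.copy()
        pheno["case"] = 0
        pheno.iloc[:2, pheno.columns.get_loc("case")] = 1
        with pytest.raises(ValueError, match="three cases"):
            pc_time_association(pc, pheno)


class TestCrossCorrelation:
    def test_self_correlation_identity(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(6, 50)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(50)],
        )
        pc = pca_gene_set(matrix, [f"G{i}" for i in range(6)])
        cc = pc_cross_correlation(pc, pc)
        np.testing.assert_allclose(np.abs(np.diag(cc.to_numpy())), 1.0, atol=1e-12)

    def test_shared_latent_factor_links_pc1(self, rng):
        factor = rng.normal(size=80)
        mk = lambda k: pd.DataFrame(
            {f"{k}{i}": factor + rng.normal(scale=1.0, size=80) for i in range(6)}
        ).T.set_axis([f"s{i}" for i in range(80)], axis=1)
        a = pca_gene_set(mk("A"), [f"A{i}" for i in range(6)], "a")
        b = pca_gene_set(mk("B"), [f"B{i}" for i in range(6)], "b")
        cc = pc_cross_correlation(a, b)
        assert abs(cc.iloc[0, 0]) > 0.8

    def test_misaligned_samples_error(self, rng):
        m1 = pd.DataFrame(rng.normal(size=(4, 20)), index=list("ABCD"),
                          columns=[f"s{i}" for i in range(20)])
        m2 = m1.rename(columns={"s0": "zz"})
        a = pca_gene_set(m1, list("ABCD"), "a")
        b = pca_gene_set(m2, list("ABCD"), "b")
        with pytest.raises(ValueError, match="different samples"):
            pc_cross_correlation(a, b)


class TestEnrichment:
    def test_set_equal_to_universe_is_unenrichable(self):
        universe = [f"G{i}" for i in range(50)]
        sets = {"ALL": {"description": "", "genes": universe}}
        table = geneset_enrichment(universe[:10], universe, sets)
        assert table.loc[0, "p"] == 1.0

    def test_exactly_significant_set_is_point_mass(self):
        universe = [f"G{i}" for i in range(30)]
        sig = universe[:6]
        sets = {"HIT": {"description": "", "genes": sig}}
        table = geneset_enrichment(sig, universe, sets)
        point = Fraction(comb(6, 6) * comb(24, 0), comb(30, 6))
        assert table.loc[0, "p"] == pytest.approx(float(point), rel=1e-9)

    def test_loaded_set_flagged_only(self, rng):
        universe = [f"G{i}" for i in range(400)]
        sig = universe[:25]
        sets = {"LOADED": {"description": "", "genes": sig[:20]}}
        for i in range(4):
            sets[f"RND{i}"] = {
                "description": "",
                "genes": sorted(rng.choice(universe, 30, replace=False)),
            }
        table = geneset_enrichment(sig, universe, sets).set_index("set_id")
        assert table.at["LOADED", "bonferroni_flag"]
        assert not table.drop("LOADED")["bonferroni_flag"].any()

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            geneset_enrichment([], [], {"S": {"description": "", "genes": ["G"]}})


class TestCompositionTest:
    @staticmethod
    def _calls(labels):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(labels))], "label": labels}
        )

    def test_identical_proportions_give_p_one(self):
        labels = ["++"] * 10 + ["o+"] * 10
        calls = self._calls(labels)
        members = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(10, 15)]
        res = category_composition_test(members, calls)
        assert not res["skipped"]
        assert res["p"] == pytest.approx(1.0, abs=1e-9)

    def test_concentrated_set_gets_small_p(self):
        labels = ["++"] * 8 + ["o+"] * 40
        calls = self._calls(labels)
        members = [f"g{i}" for i in range(8)]  # all of, and only, the '++' genes
        res = category_composition_test(members, calls)
        oracle = exact_2xk_enumeration([8, 0], [0, 40])
        assert res["p"] == pytest.approx(oracle, rel=1e-9)
        assert res["p"] < 1e-6

    def test_counts_conserve_universe(self):
        labels = ["++", "--", "o+", "+o", "-+", "oo", "o-"]
        calls = self._calls(labels)
        res = category_composition_test(["g0", "g2"], calls)
        total = sum(v["inside"] + v["outside"] for v in res["counts"].values())
        assert total == sum(1 for l in labels if l != "oo")

    def test_single_category_skipped(self):
        calls = self._calls(["++", "++", "oo"])
        res = category_composition_test(["g0"], calls)
        assert res["skipped"] and res["p"] is None

    def test_exact_matches_enumeration_on_random_tables(self, rng):
        for _ in range(60):
            k = rng.integers(2, 5)
            row1 = rng.integers(0, 8, size=k)
            row2 = rng.integers(0, 12, size=k)
            if row1.sum() == 0 or (row1 + row2 == 0).any():
                continue
            mine = exact_2xk_test(row1, row2)
            oracle = exact_2xk_enumeration(list(row1), list(row2))
            assert mine["p"] == pytest.approx(oracle, rel=1e-9), (row1, row2)


class TestDriverLookup:
    def test_empty_list(self):
        calls = pd.DataFrame(
            {"gene": ["g0"], "label": ["oo"], "tier": ["none"],
             "clinical_bonferroni": [False], "prediag_bonferroni": [False],
             "clinical_nominal": [False], "prediag_nominal": [False]}
        )
        meta = pd.DataFrame({"gene": ["g0"], "p": [0.5]})
        pre = pd.DataFrame({"gene": ["g0"], "p": [0.5]})
        table, summary = driver_gene_lookup([], calls, meta, pre)
        assert len(table) == 0
        assert summary["n_listed"] == 0

    def test_absent_genes_flagged_and_excluded(self):
        calls = pd.DataFrame(
            {"gene": ["g0", "g1"], "label": ["++", "oo"], "tier": ["nominal", "none"],
             "clinical_bonferroni": [False, False], "prediag_bonferroni": [True, False],
             "clinical_nominal": [True, False], "prediag_nominal": [True, False]}
        )
        meta = pd.DataFrame({"gene": ["g0", "g1"], "p": [0.01, 0.9]})
        pre = pd.DataFrame({"gene": ["g0", "g1"], "p": [1e-7, 0.8]})
        table, summary = driver_gene_lookup(["g0", "MISSING"], calls, meta, pre)
        assert summary["n_present"] == 1 and summary["n_absent"] == 1
        assert not table.set_index("gene").at["MISSING", "in_universe"]
        assert summary["n_prediag_bonferroni"] == 1
        assert summary["n_concordant"] == 1


def test_gene_correlation_structure_orders_blocks(rng):
    f1, f2 = rng.normal(size=50), rng.normal(size=50)
    rows = {}
    for i in range(4):
        rows[f"A{i}"] = f1 + rng.normal(scale=0.3, size=50)
    for i in range(4):
        rows[f"B{i}"] = f2 + rng.normal(scale=0.3, size=50)
    matrix = pd.DataFrame(rows).T.set_axis([f"s{i}" for i in range(50)], axis=1)
    genes = ["A0", "B0", "A1", "B1", "A2", "B2", "A3", "B3"]
    corr, order = gene_correlation_structure(matrix, genes)
    # average-linkage ordering should separate the two correlation blocks
    groups = ["".join(g[0] for g in order)]
    assert groups[0] in ("AAAABBBB", "BBBBAAAA")
    assert corr.shape == (8, 8)
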