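"""Global Z-test, site-wise methods, consensus rule and reports."""

import numpy as np
import pandas as pd
import pytest

from equimhc.phylo import Node, Tree, jc_distance_matrix, nj_tree
from equimhc.selection import (
    consensus_sites,
    deleterious_by_all_tools,
    fel_sites,
    global_z_test,
    saas_report,
    slac_sites,
    variant_substitutions,
)
from equimhc.seq_io import CodonAlignment
from equimhc.synthetic import (
    allele_genealogy,
    neutral_model,
    simulate_codon_alignment,
    two_class_model,
)


def nj_from(aln):
    mat, ids = jc_distance_matrix(aln)
    return nj_tree(mat, ids)


class TestGlobalZTest:
    def test_invariant_alignment_degenerates_to_p_one(self, make_alignment):
        aln = make_alignment(["ATGAAACCG"] * 4)
        z = global_z_test(aln, n_boot=100, seed=0)
        assert z.Z == 0.0 and z.p_one_tailed == 1.0

    def test_negative_statistic_reports_p_one(self, make_alignment):
        # purely synonymous differences -> dS > dN -> one-tailed p = 1
        aln = make_alignment(["ATGAAACCGGGA", "ATGAAGCCAGGG",
                              "ATGAAACCTGGC", "ATGAAGCCCGGT"])
        z = global_z_test(aln, n_boot=500, seed=1)
        assert z.mean_dN_minus_dS < 0
        assert z.p_one_tailed == 1.0

    def test_seeded_reproducibility(self):
        aln = simulate_codon_alignment(
            allele_genealogy(10, seed=3), neutral_model(60), seed=3
        )
        z1 = global_z_test(aln, n_boot=200, seed=9)
        z2 = global_z_test(aln, n_boot=200, seed=9)
        assert z1 == z2

    def test_stop_flagged_rows_are_excluded(self, make_alignment):
        aln = make_alignment(["ATGAAACCG", "ATGAAGCCG", "TAAAAACCG"])
        aln.stop_flagged = {2}
        z = global_z_test(aln, n_boot=100, seed=0)
        # identical to the test without the pseudogene-like row
        ref = global_z_test(make_alignment(["ATGAAACCG", "ATGAAGCCG"]),
                            n_boot=100, seed=0)
        assert z.mean_dN_minus_dS == pytest.approx(ref.mean_dN_minus_dS)

    def test_fewer_than_two_analyzable_rows_rejected(self, make_alignment):
        aln = make_alignment(["ATGAAACCG", "TAAAAACCG"])
        aln.stop_flagged = {1}
        with pytest.raises(ValueError):
            global_z_test(aln)


class TestSLAC:
    def test_invariant_column_has_no_changes(self, make_alignment):
        aln = make_alignment(["ATGAAA"] * 4)
        tree = Tree(Node())
        for i in range(4):
            tree.root.add(Node(f"s{i}", 0.1))
        table = slac_sites(aln, tree)
        assert (table["Sd"] == 0).all() and (table["Nd"] == 0).all()
        assert (table["class"] == "none").all()

    def test_single_terminal_nonsynonymous_change_hand_case(self, make_alignment):
        # 4 taxa: three share ATG AAA; one carries ATG AAC (Lys->Asn, one
        # nonsynonymous change on its terminal branch under parsimony)
        aln = make_alignment(["ATGAAA", "ATGAAA", "ATGAAA", "ATGAAC"])
        root = Node()
        for i in range(4):
            root.add(Node(f"s{i}", 0.1))
        table = slac_sites(aln, Tree(root))
        site2 = table.set_index("site").loc[2]
        assert site2["Nd"] == 1.0 and site2["Sd"] == 0.0

    def test_tree_alignment_mismatch_rejected(self, make_alignment):
        aln = make_alignment(["ATGAAA", "ATGAAC"], ids=["a", "b"])
        root = Node()
        root.add(Node("a", 0.1))
        root.add(Node("zzz", 0.1))
        with pytest.raises(ValueError):
            slac_sites(aln, Tree(root))


class TestFEL:
    def test_invariant_site_reports_null_rates(self, make_alignment):
        aln = make_alignment(["ATGAAA", "ATGAAC", "ATGAAA", "ATGAAC"])
        tree = nj_from(aln)
        table = fel_sites(aln, tree)
        site1 = table.set_index("site").loc[1]
        assert site1["alpha"] == 0.0 and site1["beta"] == 0.0
        assert site1["p"] == 1.0 and site1["class"] == "none"

    def test_calibration_under_equal_rates(self):
        """With beta = alpha (neutral simulation), the per-site LRT rejects
        at most ~10% of variable sites at the 0.1 threshold."""
        flags = []
        for rep in range(12):
            aln = simulate_codon_alignment(
                allele_genealogy(12, seed=400 + rep), neutral_model(60),
                seed=500 + rep,
            )
            table = fel_sites(aln, nj_from(aln))
            flags.extend((table["class"] != "none") & (table["p"] <= 0.1))
        assert np.mean(flags) <= 0.12

    def test_high_omega_sites_get_beta_above_alpha(self):
        hits = 0
        for rep in range(5):
            model = two_class_model(60, abs_fraction=0.4, omega_abs=5.0,
                                    omega_background=1.0, seed=rep)
            aln = simulate_codon_alignment(
                allele_genealogy(16, seed=600 + rep), model, seed=700 + rep
            )
            table = fel_sites(aln, nj_from(aln))
            sel = np.array([c == "ABS" for c in model.class_of_codon])
            beta_up = (table["beta"] > table["alpha"]).to_numpy()
            hits += beta_up[sel].mean() > beta_up[~sel].mean()
        assert hits >= 4


class TestConsensus:
    @staticmethod
    def table(classes):
        return pd.DataFrame(
            {"site": range(1, len(classes) + 1), "class": classes}
        )

    def test_single_method_flag_is_not_consensus(self):
        cons = consensus_sites({
            "SLAC": self.table(["positive", "none"]),
            "FEL": self.table(["none", "none"]),
        })
        assert list(cons["consensus"]) == ["none", "none"]

    def test_two_methods_agreeing_make_consensus(self):
        cons = consensus_sites({
            "SLAC": self.table(["positive", "negative"]),
            "FEL": self.table(["positive", "negative"]),
        })
        assert list(cons["consensus"]) == ["positive", "negative"]

    def test_requires_at_least_two_tables(self):
        with pytest.raises(ValueError):
            consensus_sites({"SLAC": self.table(["positive"])})

    def test_empty_tables_give_all_none(self):
        cons = consensus_sites({
            "SLAC": self.table(["none"] * 3),
            "FEL": self.table(["none"] * 3),
        })
        assert (cons["consensus"] == "none").all()

    def test_adding_a_method_only_grows_the_consensus_set(self):
        two = consensus_sites({
            "SLAC": self.table(["positive", "none", "positive"]),
            "FEL": self.table(["positive", "positive", "none"]),
        })
        three = consensus_sites({
            "SLAC": self.table(["positive", "none", "positive"]),
            "FEL": self.table(["positive", "positive", "none"]),
            "MEME": self.table(["none", "positive", "positive"]),
        })
        before = set(two.loc[two["consensus"] == "positive", "site"])
        after = set(three.loc[three["consensus"] == "positive", "site"])
        assert before <= after

    def test_abs_annotation(self):
        cons = consensus_sites(
            {"SLAC": self.table(["positive"]), "FEL": self.table(["positive"])},
            abs_codons={1},
        )
        assert bool(cons.iloc[0]["is_ABS"])


class TestReports:
    def test_locus_without_selected_sites_has_zero_saas(self, make_alignment):
        aln = make_alignment(["ATGAAA"] * 3)
        cons = consensus_sites({
            "SLAC": TestConsensus.table(["none", "none"]),
            "FEL": TestConsensus.table(["none", "none"]),
        })
        report = saas_report({"DQB3": cons}, {"DQB3": aln}, {"DQB3": set()})
        row = report["summary"].set_index("locus").loc["DQB3"]
        assert row["n_SAAS"] == 0 and row["n_positive"] == 0

    def test_constructed_saas_fall_inside_abs(self, make_alignment):
        # variation at codon 2 only; both methods call it positive; ABS = {2}
        aln = make_alignment(["ATGAAACCG", "ATGCGACCG", "ATGAAACCG"])
        cons = consensus_sites(
            {
                "SLAC": TestConsensus.table(["none", "positive", "none"]),
                "FEL": TestConsensus.table(["none", "positive", "none"]),
            },
            abs_codons={2},
        )
        report = saas_report({"DQB1": cons}, {"DQB1": aln}, {"DQB1": {2}})
        variants = report["variants"]
        saas_rows = variants[variants["is_SAAS"]]
        assert len(saas_rows) >= 1
        assert saas_rows["is_ABS"].all()

    def test_deleterious_requires_both_tools(self):
        predictors = pd.DataFrame({
            "site": [2, 2, 3],
            "substitution": ["K->R", "K->R", "P->T"],
            "tool": ["provean", "polyphen", "provean"],
            "deleterious": [1, 1, 1],
        })
        both = deleterious_by_all_tools(predictors)
        assert list(both["site"]) == [2]  # P->T seen by one tool only

    def test_variant_substitutions_reference_is_majority(self, make_alignment):
        aln = make_alignment(["AAA", "AAA", "AGA"])
        table = variant_substitutions(aln)
        assert list(table["substitution"]) == ["K->R"]
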