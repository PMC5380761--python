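"""MD ortholog-group extraction, complexity, presence/absence, summaries."""

import pandas as pd
import pytest

from corekit.datasets import load_og_counts
from corekit.og_extraction import (
    COMPLEX,
    SIMPLE,
    FamilyCensus,
    OGParams,
    classify_complexity,
    detect_clade_absence,
    find_md_ogs,
    presence_absence,
    summarize_ogs,
)
from corekit.reconciliation import lca_map
from corekit.synthetic_data import (
    SimulationConfig,
    assign_supports,
    simulate_gene_family,
)
from corekit.trees import parse_newick


def _md_clade(copy: int, root_support: str = "0.99") -> str:
    """A clean monocot/dicot clade over stree10 (4 monocot, 5 dicot)."""
    g = lambda s: f"{s}_{copy}"  # noqa: E731
    mono = f"(({g('A')},{g('B')})0.99,({g('C')},{g('D')})0.99)0.99"
    dico = (
        f"(({g('E')},{g('F')})0.99,(({g('G')},{g('H')})0.99,{g('I')})0.99)0.99"
    )
    return f"({mono},{dico}){root_support}"


class TestFindMDOGs:
    def test_two_clean_clades_give_two_ogs(self, stree10):
        tree = parse_newick(f"({_md_clade(1)},{_md_clade(2)})1.0;")
        ogs = find_md_ogs(tree, stree10)
        assert len(ogs) == 2
        assert all(og.classification == SIMPLE for og in ogs)
        assert all(og.size == 9 for og in ogs)

    def test_support_at_threshold_boundary_is_excluded(self, stree10):
        """The support filter is a strict > 0.85."""
        tree = parse_newick(
            f"({_md_clade(1, '0.80')},{_md_clade(2)})1.0;"
        )
        ogs = find_md_ogs(tree, stree10)
        assert len(ogs) == 1
        assert sorted(og_member.split("_")[1] for og_member in ogs[0].members) == ["2"] * 9
        tree2 = parse_newick(
            f"({_md_clade(1, '0.85')},{_md_clade(2)})1.0;"
        )
        assert len(find_md_ogs(tree2, stree10)) == 1
        tree3 = parse_newick(
            f"({_md_clade(1, '0.851')},{_md_clade(2)})1.0;"
        )
        assert len(find_md_ogs(tree3, stree10)) == 2

    def test_too_few_monocot_species_rejected(self, stree10):
        mono = "(A_1,B_1)0.99"  # only 2 monocot species
        dico = "((E_1,F_1)0.99,((G_1,H_1)0.99,I_1)0.99)0.99"
        tree = parse_newick(f"(({mono},{dico})0.99,O_1);")
        assert find_md_ogs(tree, stree10) == []

    def test_intermingled_clade_reported_as_complex(self, stree10):
        clade = (
            "((A_1,E_1)0.99,((B_1,F_1)0.99,((C_1,G_1)0.99,"
            "(H_1,I_1)0.99)0.99)0.99)0.99"
        )
        tree = parse_newick(f"({clade},O_1);")
        ogs = find_md_ogs(tree, stree10)
        assert len(ogs) == 1
        assert ogs[0].classification == COMPLEX
        assert ogs[0].size == 8

    def test_missing_supports_rejected(self, stree10):
        tree = parse_newick("((A_1,B_1),(E_1,(F_1,(G_1,H_1))));")
        with pytest.raises(ValueError, match="support"):
            find_md_ogs(tree, stree10)

    def test_untagged_species_rejected_by_name(self, stree10):
        tree = parse_newick(f"({_md_clade(1)},ZZZ_1);")
        with pytest.raises(ValueError, match="ZZZ"):
            find_md_ogs(tree, stree10)

    def test_reported_ogs_are_leaf_disjoint(self, stree33):
        cfg = SimulationConfig(
            duplication_rate=0.15, loss_rate=0.05, seed=21
        )
        truth = simulate_gene_family(stree33, cfg)
        assign_supports(truth, cfg)
        ogs = find_md_ogs(truth.root, stree33)
        seen: set = set()
        for og in ogs:
            members = set(og.members)
            assert not members & seen
            seen |= members

    def test_lower_threshold_never_reports_fewer_ogs(self, stree33):
        for seed in range(6):
            cfg = SimulationConfig(
                duplication_rate=0.12,
                loss_rate=0.03,
                seed=seed,
                support_noise_sd=0.12,
            )
            truth = simulate_gene_family(stree33, cfg)
            if truth.root is None or truth.root.is_leaf:
                continue
            assign_supports(truth, cfg)
            n_high = len(
                find_md_ogs(
                    truth.root, stree33, OGParams(support_threshold=0.95)
                )
            )
            n_low = len(
                find_md_ogs(
                    truth.root, stree33, OGParams(support_threshold=0.5)
                )
            )
            assert n_low >= n_high


class TestComplexity:
    def _extract_single(self, newick, stree):
        tree = parse_newick(newick)
        ogs = find_md_ogs(tree, stree)
        assert len(ogs) == 1
        return tree, ogs[0]

    def test_duplication_free_og_is_simple(self, stree10):
        tree, og = self._extract_single(
            f"({_md_clade(1)},O_1);", stree10
        )
        rec = lca_map(tree, stree10)
        assert classify_complexity(og, rec) == SIMPLE

    def test_species_terminal_duplication_ignored(self, stree10):
        """Paralogs arising within one species do not make an OG complex."""
        mono = "(((A_1,A_2)0.99,(B_1,(B_2,B_3)0.99)0.99)0.99,(C_1,D_1)0.99)0.99"
        dico = "((E_1,F_1)0.99,((G_1,H_1)0.99,I_1)0.99)0.99"
        tree, og = self._extract_single(
            f"(({mono},{dico})0.99,O_1);", stree10
        )
        rec = lca_map(tree, stree10)
        assert classify_complexity(og, rec) == SIMPLE

    def test_two_ancestral_duplications_make_complex(self, stree10):
        mono = "((A_1,B_1)0.99,(C_1,D_1)0.99)0.99"
        dico = (
            "(((E_1,F_1)0.99,(E_2,F_2)0.99)0.99,"
            "((G_1,(H_1,I_1)0.99)0.99,(G_2,(H_2,I_2)0.99)0.99)0.99)0.99"
        )
        tree, og = self._extract_single(
            f"(({mono},{dico})0.99,O_1);", stree10
        )
        rec = lca_map(tree, stree10)
        assert classify_complexity(og, rec) == COMPLEX


class TestPresenceAbsence:
    def test_full_matrix_has_no_zeros_and_conserved_row_sums(self, stree10):
        tree = parse_newick(f"({_md_clade(1)},{_md_clade(2)})1.0;")
        ogs = find_md_ogs(tree, stree10)
        matrix = presence_absence(ogs, list("ABCDEFGHI"))
        assert (matrix > 0).all().all()
        assert list(matrix.sum(axis=1)) == [og.size for og in ogs]

    def test_missing_species_yields_single_zero(self, stree10):
        clade2 = (
            "(((A_2,B_2)0.99,(C_2,D_2)0.99)0.99,"
            "((E_2,F_2)0.99,(G_2,H_2)0.99)0.99)0.99"
        )  # species I absent
        tree = parse_newick(f"({_md_clade(1)},{clade2})1.0;")
        ogs = find_md_ogs(tree, stree10)
        matrix = presence_absence(ogs, list("ABCDEFGHI"))
        assert (matrix == 0).sum().sum() == 1
        assert matrix.loc[ogs[1].og_id, "I"] == 0


class TestCladeAbsence:
    def _matrix(self):
        cols = ["ARATH", "ARALY", "BRARA", "EUTSA", "SCHPA", "CARPA", "VITVI"]
        return pd.DataFrame(
            {
                "OG_brassicales_lost": [0, 0, 0, 0, 0, 0, 2],
                "OG_brassicaceae_lost": [0, 0, 0, 0, 0, 1, 2],
                "OG_kept": [1, 2, 1, 1, 1, 1, 1],
            },
            index=cols,
        ).T

    def test_full_matrix_gives_empty_list(self):
        m = self._matrix().loc[["OG_kept"]]
        assert detect_clade_absence(m, ["ARATH", "ARALY"]) == []

    def test_nested_clades_distinguish_losses(self):
        m = self._matrix()
        brassicaceae = ["ARATH", "ARALY", "BRARA", "EUTSA", "SCHPA"]
        brassicales = brassicaceae + ["CARPA"]
        assert detect_clade_absence(m, brassicaceae) == [
            "OG_brassicales_lost",
            "OG_brassicaceae_lost",
        ]
        assert detect_clade_absence(m, brassicales) == [
            "OG_brassicales_lost"
        ]

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_clade_absence(self._matrix(), [])


class TestSummaries:
    def test_printed_census_arithmetic(self):
        census = FamilyCensus(
            total_sequences=8360,
            outgroup_counts={"PHYPA": 134, "SELML": 81},
            complex_genes=2956,
            complex_ogs=24,
            noncomplex_genes=3783,
            noncomplex_ogs=77,
            og_counts=load_og_counts(),
        )
        s = summarize_ogs(census)
        assert s["genes_in_ogs"] == 6739
        assert s["mean_genes_per_complex_og"] == 123.2
        assert s["mean_genes_per_noncomplex_og"] == 49.1
        assert s["pct_angiosperm_genes_in_ogs"] == 82.7
        assert s["total_ogs"] == 101
        assert s["total_complex_ogs"] == 24

    def test_empty_census_gives_zeros(self):
        s = summarize_ogs(FamilyCensus())
        assert s["genes_in_ogs"] == 0
        assert s["mean_genes_per_complex_og"] == 0.0
        assert s["pct_angiosperm_genes_in_ogs"] == 0.0

    def test_inconsistent_census_rejected_with_identity(self):
        census = FamilyCensus(
            complex_ogs=24,
            noncomplex_ogs=70,  # should be 77
            og_counts=load_og_counts(),
        )
        with pytest.raises(ValueError, match="101"):
            summarize_ogs(census)
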