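"""Ground-truth generators: gene families, supports, proteins, branch tests."""

import numpy as np
import pytest
from scipy.stats import kstest

from corekit.domain_architecture import annotate
from corekit.reconciliation import count_events, lca_map
from corekit.selection_stats import DomainPartition, filter_beb_sites, lrt_pvalue
from corekit.synthetic_data import (
    ArchitectureSpec,
    BranchTestTruth,
    SimulationConfig,
    assign_supports,
    simulate_branch_test,
    simulate_gene_family,
    simulate_protein,
    write_fixture_bundle,
)
from corekit.trees import write_newick


class TestGeneFamilySimulation:
    def test_zero_rates_give_species_tree_congruence(self, stree33):
        cfg = SimulationConfig(duplication_rate=0, loss_rate=0, seed=5)
        truth = simulate_gene_family(stree33, cfg)
        assert sorted(
            n.split("_")[0] for n in truth.root.leaf_names()
        ) == sorted(stree33.species)
        assert set(truth.events.values()) == {"speciation"}
        assert truth.loss_total() == 0
        assert count_events(lca_map(truth.root, stree33)) == (0, 0)

    def test_forced_root_duplication_doubles_a_congruent_family(self, stree3):
        cfg = SimulationConfig(
            duplication_rate=0,
            loss_rate=0,
            seed=0,
            forced_root_duplications=1,
        )
        truth = simulate_gene_family(stree3, cfg)
        assert len(truth.root.leaves()) == 6
        events = list(truth.events.values())
        assert events.count("duplication") == 1
        assert truth.root.event == "duplication"
        # two congruent copies under the duplication
        for side in truth.root.children:
            assert sorted(n.split("_")[0] for n in side.leaf_names()) == [
                "A",
                "B",
                "C",
            ]

    def test_same_seed_reproduces_newick_byte_identically(self, stree33):
        cfg = SimulationConfig(duplication_rate=0.1, loss_rate=0.05, seed=11)
        a = simulate_gene_family(stree33, cfg)
        b = simulate_gene_family(stree33, cfg)
        assert write_newick(a.root) == write_newick(b.root)

    def test_negative_rates_rejected(self, stree3):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_gene_family(
                stree3, SimulationConfig(duplication_rate=-1)
            )

    def test_nonbinary_species_tree_rejected(self, stree3):
        from corekit.species import SpeciesTree
        from corekit.trees import parse_newick

        bad = SpeciesTree(
            parse_newick("(A,B,C);"),
            {"A": "monocot", "B": "monocot", "C": "dicot"},
        )
        with pytest.raises(ValueError, match="binary"):
            simulate_gene_family(bad, SimulationConfig())

    def test_losses_recorded_when_loss_rate_high(self, stree33):
        cfg = SimulationConfig(duplication_rate=0.0, loss_rate=0.4, seed=2)
        truth = simulate_gene_family(stree33, cfg)
        assert truth.loss_total() > 0


class TestSupports:
    def test_zero_noise_gives_unit_supports(self, stree33):
        cfg = SimulationConfig(duplication_rate=0, loss_rate=0, seed=1)
        truth = simulate_gene_family(stree33, cfg)
        root = assign_supports(truth, cfg)
        assert all(
            n.support == 1.0 for n in root.internal_nodes()
        )

    def test_targeted_override_places_single_low_support(self, stree33):
        cfg = SimulationConfig(duplication_rate=0, loss_rate=0, seed=1)
        truth = simulate_gene_family(stree33, cfg)
        target = next(
            n
            for n in truth.root.internal_nodes()
            if n.parent is not None
        ).leaf_names()
        cfg.support_overrides = {frozenset(target): 0.80}
        root = assign_supports(truth, cfg)
        low = [
            n.support for n in root.internal_nodes() if n.support < 0.85
        ]
        assert low == [0.80]

    def test_noisy_supports_deterministic_and_in_range(self, stree33):
        cfg = SimulationConfig(
            duplication_rate=0, loss_rate=0, seed=4, support_noise_sd=0.1
        )
        t1 = simulate_gene_family(stree33, cfg)
        t2 = simulate_gene_family(stree33, cfg)
        s1 = [n.support for n in assign_supports(t1, cfg).internal_nodes()]
        s2 = [n.support for n in assign_supports(t2, cfg).internal_nodes()]
        assert s1 == s2
        assert all(0.0 <= s <= 1.0 for s in s1)


class TestProteinSimulation:
    def test_no_lrr_homolog_has_empty_lrr_list(self):
        spec = ArchitectureSpec(
            n_lrr=0, cys_pair_n=False, cys_pair_c=False, has_kd=True
        )
        seq, truth = simulate_protein(spec, seed=1)
        assert truth.n_lrr == 0 and truth.lrr_hits == []
        assert truth.has_kd

    def test_island_of_60_residues_after_lrr_13(self):
        spec = ArchitectureSpec(n_lrr=21, islands=[(13, 60)])
        _, truth = simulate_protein(spec, seed=2)
        assert truth.n_lrr == 21
        assert [i.length for i in truth.islands] == [60]
        assert truth.islands[0].lrr_equivalents == 2

    def test_scan_round_trip_recovers_lrrs_and_cys_pairs(self):
        spec = ArchitectureSpec(n_lrr=5, cys_pair_n=True, cys_pair_c=True)
        seq, truth = simulate_protein(spec, seed=3)
        arch = annotate(seq)
        assert arch.n_lrr == 5
        assert [(h.start, h.end) for h in arch.lrr_hits] == [
            (h.start, h.end) for h in truth.lrr_hits
        ]
        assert (arch.cys_pair_n, arch.cys_pair_c) == (True, True)

    def test_oversized_island_rejected(self):
        spec = ArchitectureSpec(n_lrr=10, islands=[(4, 999)])
        with pytest.raises(ValueError, match="maximum"):
            simulate_protein(spec, seed=0)


class TestBranchTestSimulation:
    def test_null_has_no_passing_beb_sites(self):
        truth = BranchTestTruth(
            branch_id="b1",
            has_selection=False,
            partition=DomainPartition((("ECD", 50), ("ICD", 50))),
        )
        res = simulate_branch_test(truth, seed=9)
        assert all(s.posterior < 0.95 for s in res.sites)
        assert filter_beb_sites(res.sites) == []

    def test_fixed_seed_reproduces_lnl_pair(self):
        truth = BranchTestTruth(branch_id="b1")
        a = simulate_branch_test(truth, seed=13)
        b = simulate_branch_test(truth, seed=13)
        assert (a.lnl0, a.lnl1) == (b.lnl0, b.lnl1)

    def test_true_sites_require_selection_flag(self):
        with pytest.raises(ValueError, match="has_selection"):
            BranchTestTruth(
                branch_id="b", has_selection=False, true_sites=(3,)
            ).validate()

    def test_null_pvalues_uniform(self):
        """Without selection the LRT p-values are U(0,1) (KS at alpha=0.01)."""
        part = DomainPartition((("ECD", 5), ("ICD", 5)))
        ps = []
        for i in range(5000):
            res = simulate_branch_test(
                BranchTestTruth(branch_id="b", partition=part), seed=i
            )
            ps.append(lrt_pvalue(res)[1])
        assert kstest(np.array(ps), "uniform").pvalue > 0.01


class TestFixtureBundle:
    def test_bundle_includes_packaged_tables(self, tmp_path):
        import pandas as pd

        written = write_fixture_bundle({}, tmp_path)
        names = {p.name for p in written}
        assert {"table1.tsv", "table2.tsv", "proteins.fasta"} <= names
        t2 = pd.read_csv(tmp_path / "table2.tsv", sep="\t")
        assert len(t2) == 24
        t1 = pd.read_csv(tmp_path / "table1.tsv", sep="\t")
        assert len(t1) == 20

    def test_empty_simulation_writes_valid_empty_files(self, tmp_path):
        written = write_fixture_bundle(
            {"proteins": [], "branch_tests": []}, tmp_path
        )
        fasta = tmp_path / "proteins.fasta"
        assert fasta.read_text() == ""
        branch = (tmp_path / "branch_tests.tsv").read_text().splitlines()
        assert branch[0].split("\t") == ["branch", "np0", "lnl0", "np1", "lnl1"]
        assert len(branch) == 1
        assert all(p.exists() for p in written)
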