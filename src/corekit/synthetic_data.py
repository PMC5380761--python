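"""Synthetic gene families, receptor sequences and branch-test records.

Every downstream stage of the pipeline (architecture annotation,
reconciliation, ortholog-group extraction, selection post-processing) is
exercised against data generated here with known ground truth:

* gene families evolve by a birth–death copy process along a rooted species
  tree (one starting copy at the root; exponential waiting times for
  duplication/loss on every edge; every surviving copy bifurcates at each
  speciation node);
* protein sequences are assembled from an explicit architecture
  specification (SP – [MLD] – Cys pair – LRR block with islands – Cys pair –
  TM – KD), with the 24-residue LRR consensus instantiated at its 11
  canonical positions and the 13 free positions drawn at random;
* branch-site test records draw the likelihood-ratio statistic directly
  from its sampling distribution (central chi-square df=1 without selection,
  noncentral with) rather than simulating codon evolution — the pipeline
  under test is the post-processing, not the likelihood optimiser.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain_architecture import (
    DomainArchitecture,
    Island,
    LRRMotifSpec,
    MotifHit,
)
from .selection_stats import BranchTestResult, DomainPartition, SiteRecord
from .species import SpeciesTree
from .trees import Node, write_newick

__all__ = [
    "SimulationConfig",
    "GeneTreeTruth",
    "ArchitectureSpec",
    "BranchTestTruth",
    "simulate_gene_family",
    "assign_supports",
    "simulate_protein",
    "random_architecture_spec",
    "simulate_branch_test",
    "write_fixture_bundle",
]

# residues used at non-canonical LRR positions, in linkers, islands and the
# MLD placeholder: hydrophilic, no Cys, and disjoint from the canonical
# consensus residues so random stretches can never mimic an LRR unit
FREE_RESIDUES = "ADEHKQRT"
HYDROPHOBIC_RESIDUES = "LIVFA"


@dataclass
class SimulationConfig:
    """Parameters of the gene-family birth–death simulation.

    Rates are events per gene copy per unit branch length. Per-clade
    multipliers scale both rates on species-tree edges whose entire subtree
    lies within the named clade or subclade. ``forced_root_duplications``
    deterministically duplicates the starting copy above the species root,
    for constructing histories with known ancient duplications.
    """

    duplication_rate: float = 0.1
    loss_rate: float = 0.05
    seed: int = 0
    support_noise_sd: float = 0.0
    support_overrides: dict[frozenset, float] = field(default_factory=dict)
    clade_rate_multipliers: dict[str, float] = field(default_factory=dict)
    forced_root_duplications: int = 0

    def validate(self) -> None:
        if not (
            math.isfinite(self.duplication_rate)
            and math.isfinite(self.loss_rate)
        ):
            raise ValueError("rates must be finite")
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class GeneTreeTruth:
    """A simulated gene tree with its generating history.

    ``mapping`` sends every gene node to the species node it arose at (the
    child end of its edge, for duplications); internal nodes carry their true
    event on ``Node.event``; ``losses`` aggregates loss events per
    species-tree edge (keyed by the edge's child node); ``true_ogs`` lists
    the leaf sets of the true monocot/dicot ortholog groups.
    """

    root: Optional[Node]
    species_tree: SpeciesTree
    mapping: dict[Node, Node] = field(default_factory=dict)
    losses: dict[Node, int] = field(default_factory=dict)
    true_ogs: list[frozenset] = field(default_factory=list)

    @property
    def events(self) -> dict[Node, str]:
        if self.root is None:
            return {}
        return {
            n: n.event for n in self.root.preorder() if n.event is not None
        }

    def loss_total(self) -> int:
        return sum(self.losses.values())


def _subtree_tags(stree: SpeciesTree) -> dict[int, set]:
    """Clade/subclade names covering the whole subtree of each species node."""
    cover: dict[int, set] = {}
    for node in stree.root.postorder():
        if node.is_leaf:
            tags = {stree.clade_tags[node.name]}
            tags |= stree.subclade_tags.get(node.name, frozenset())
            cover[id(node)] = tags
        else:
            tags = set.intersection(
                *(cover[id(c)] for c in node.children)
            )
            cover[id(node)] = tags
    return cover


def simulate_gene_family(
    species_tree: SpeciesTree, config: SimulationConfig
) -> GeneTreeTruth:
    """Evolve one gene family along the species tree.

    A single copy starts at the species root. On every edge, each extant
    copy duplicates or dies with exponential waiting times at the configured
    rates; at every speciation node each surviving copy bifurcates. Lineages
    whose descendants all die are pruned, so the returned tree contains only
    observable nodes; all recorded events refer to surviving lineages.
    """
    config.validate()
    species_tree.validate_for_simulation()
    rng = np.random.default_rng(config.seed)
    cover = _subtree_tags(species_tree)
    mult = {
        nid: math.prod(
            m
            for tag, m in config.clade_rate_multipliers.items()
            if tag in tags
        )
        for nid, tags in cover.items()
    }
    truth = GeneTreeTruth(root=None, species_tree=species_tree)
    counters: dict[str, int] = defaultdict(int)
    losses: Counter = Counter()

    def at_node(s: Node) -> Optional[Node]:
        if s.is_leaf:
            counters[s.name] += 1
            leaf = Node(f"{s.name}_gene{counters[s.name]:03d}")
            truth.mapping[leaf] = s
            return leaf
        kids = [down_edge(c) for c in s.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node(children=kids)
        node.event = "speciation"
        truth.mapping[node] = s
        return node

    def down_edge(s: Node) -> Optional[Node]:
        return evolve(s, s.length if s.length is not None else 1.0)

    def evolve(s: Node, remaining: float) -> Optional[Node]:
        lam = config.duplication_rate * mult[id(s)]
        mu = config.loss_rate * mult[id(s)]
        total = lam + mu
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if wait >= remaining:
            return at_node(s)
        if rng.random() < lam / total:  # duplication within the edge
            left = evolve(s, remaining - wait)
            right = evolve(s, remaining - wait)
            live = [x for x in (left, right) if x is not None]
            if not live:
                return None
            if len(live) == 1:
                return live[0]
            node = Node(children=live)
            node.event = "duplication"
            truth.mapping[node] = s
            return node
        losses[id(s)] += 1
        return None

    root_copy = at_node(species_tree.root)
    for _ in range(config.forced_root_duplications):
        if root_copy is None:
            break
        other = at_node(species_tree.root)
        if other is None:
            continue
        dup = Node(children=[root_copy, other])
        dup.event = "duplication"
        truth.mapping[dup] = species_tree.root
        root_copy = dup
    truth.root = root_copy
    node_by_id = {id(n): n for n in species_tree.root.preorder()}
    truth.losses = {node_by_id[nid]: c for nid, c in losses.items()}
    truth.true_ogs = _true_md_ogs(truth)
    return truth


def _md_crown(stree: SpeciesTree) -> Node:
    """The species node splitting monocots from dicots."""
    mono = stree.members("monocot")
    dico = stree.members("dicot")
    return stree.lca(stree.leaf_by_code[mono[0]], stree.leaf_by_code[dico[0]])


def _true_md_ogs(
    truth: GeneTreeTruth, min_monocot: int = 3, min_dicot: int = 4
) -> list[frozenset]:
    """Leaf sets of gene-tree speciations at the monocot/dicot crown node
    whose subtree retains enough species of each phylum."""
    if truth.root is None:
        return []
    stree = truth.species_tree
    crown = _md_crown(stree)
    ogs = []
    for node in truth.root.preorder():
        if node.event == "speciation" and truth.mapping[node] is crown:
            leaves = node.leaf_names()
            by_clade = Counter()
            for name in leaves:
                code = name.split("_", 1)[0]
                by_clade[stree.clade_tags[code], code] = 1
            n_mono = sum(1 for (c, _s) in by_clade if c == "monocot")
            n_dico = sum(1 for (c, _s) in by_clade if c == "dicot")
            if n_mono >= min_monocot and n_dico >= min_dicot:
                ogs.append(frozenset(leaves))
    return ogs


def assign_supports(truth: GeneTreeTruth, config: SimulationConfig) -> Node:
    """Attach branch supports to every internal node of the gene tree.

    With zero noise every node gets support 1.0. Gaussian noise of the
    configured SD is subtracted (absolute value, clipped to [0, 1]).
    ``support_overrides`` maps frozensets of leaf labels to exact support
    values, for placing targeted low supports at chosen nodes.
    """
    if truth.root is None:
        raise ValueError("cannot assign supports to an empty gene tree")
    rng = np.random.default_rng(config.seed)
    for node in truth.root.preorder():
        if node.is_leaf:
            continue
        support = 1.0
        if config.support_noise_sd > 0:
            support = max(
                0.0, 1.0 - abs(rng.normal(0.0, config.support_noise_sd))
            )
        override = config.support_overrides.get(frozenset(node.leaf_names()))
        if override is not None:
            support = override
        if not 0.0 <= support <= 1.0:
            raise AssertionError("support escaped [0, 1]")
        node.support = support
    return truth.root


# -- protein sequences -----------------------------------------------------


@dataclass
class ArchitectureSpec:
    """Blueprint for one synthetic receptor sequence.

    ``islands`` lists (after-LRR-index, length-in-residues) insertions, the
    index 0-based into the LRR block. ``n_lrr = 0`` describes a ``No_LRR``
    kinase homologue.
    """

    n_lrr: int = 21
    has_sp: bool = True
    has_mld: bool = False
    mld_placement: str = "N"  # "N" or "preTM"
    mld_length: int = 100
    islands: list[tuple[int, int]] = field(default_factory=list)
    cys_pair_n: bool = True
    cys_pair_c: bool = True
    has_gdpc: bool = False
    has_tm: bool = True
    has_kd: bool = True
    linker_length: int = 12
    max_island_length: int = 300

    def validate(self) -> None:
        if self.n_lrr < 0:
            raise ValueError("n_lrr must be >= 0")
        for idx, length in self.islands:
            if not 0 <= idx < self.n_lrr:
                raise ValueError(
                    f"island index {idx} outside LRR block of {self.n_lrr}"
                )
            if length > self.max_island_length:
                raise ValueError(
                    f"island of {length} residues exceeds the configured "
                    f"maximum of {self.max_island_length}"
                )
        if self.mld_placement not in ("N", "preTM"):
            raise ValueError("mld_placement must be 'N' or 'preTM'")


def _free(rng, n: int) -> str:
    return "".join(rng.choice(list(FREE_RESIDUES), size=n))


def _hydrophobic(rng, n: int) -> str:
    return "".join(rng.choice(list(HYDROPHOBIC_RESIDUES), size=n))


def _lrr_unit(rng, spec: LRRMotifSpec) -> str:
    return "".join(
        c if c != "x" else rng.choice(list(FREE_RESIDUES))
        for c in spec.template
    )


def simulate_protein(
    spec: ArchitectureSpec,
    seed: int,
    lrr_spec: LRRMotifSpec = LRRMotifSpec(),
) -> tuple[str, DomainArchitecture]:
    """Assemble one receptor sequence and its true architecture.

    Element order: SP – [MLD] – GDPC/Cys pair – LRR block with islands –
    Cys pair – [MLD] – TM – KD. All true coordinates are 0-based half-open.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    hits: list[MotifHit] = []
    islands: list[Island] = []
    gdpc_positions: list[int] = []
    pos = 0

    def emit(fragment: str) -> int:
        nonlocal pos
        parts.append(fragment)
        start = pos
        pos += len(fragment)
        return start

    if spec.has_sp:
        start = emit("M" + _hydrophobic(rng, 20))
        hits.append(MotifHit(start, pos, "SP"))
    emit(_free(rng, spec.linker_length))
    if spec.has_mld and spec.mld_placement == "N":
        start = emit(_free(rng, spec.mld_length))
        hits.append(MotifHit(start, pos, "MLD"))
        emit(_free(rng, spec.linker_length))
    # N-side cleavage/cysteine motifs: the GDPC Cys can double as the first
    # Cys of the pair, so the pair is completed right after the motif
    if spec.has_gdpc:
        gdpc_positions.append(emit("GDPC"))
        if spec.cys_pair_n:
            emit(_free(rng, 3) + "C")
    elif spec.cys_pair_n:
        emit("C" + _free(rng, 2) + "C")
    emit(_free(rng, spec.linker_length))
    island_after = {idx: length for idx, length in spec.islands}
    lrr_indices: list[int] = []
    for i in range(spec.n_lrr):
        start = emit(_lrr_unit(rng, lrr_spec))
        hits.append(MotifHit(start, pos, "LRR"))
        lrr_indices.append(len(hits) - 1)
        if i in island_after and i + 1 < spec.n_lrr:
            istart = emit(_free(rng, island_after[i]))
            islands.append(Island(istart, pos, i, i + 1))
    emit(_free(rng, spec.linker_length))
    if spec.cys_pair_c and spec.n_lrr > 0:
        emit("C" + _free(rng, 2) + "C")
        emit(_free(rng, spec.linker_length))
    if spec.has_mld and spec.mld_placement == "preTM":
        start = emit(_free(rng, spec.mld_length))
        hits.append(MotifHit(start, pos, "MLD"))
        emit(_free(rng, spec.linker_length))
    if spec.has_tm:
        start = emit(_hydrophobic(rng, 23))
        hits.append(MotifHit(start, pos, "TM"))
        emit(_free(rng, 4))
    if spec.has_kd:
        start = emit(
            "GKGGFGEV"
            + _free(rng, 15)
            + "HRDVKAEN"
            + _free(rng, 10)
            + "DFG"
            + _free(rng, 40)
        )
        hits.append(MotifHit(start, pos, "KD"))
    sequence = "".join(parts)
    arch = DomainArchitecture(
        sequence_length=len(sequence),
        hits=sorted(hits),
        islands=islands,
        has_sp=spec.has_sp,
        has_tm=spec.has_tm,
        has_kd=spec.has_kd,
        has_mld=spec.has_mld,
        mld_placement=spec.mld_placement if spec.has_mld else None,
        cys_pair_n=spec.cys_pair_n and spec.n_lrr > 0,
        cys_pair_c=spec.cys_pair_c and spec.n_lrr > 0,
        gdpc_positions=gdpc_positions,
    )
    return sequence, arch


def random_architecture_spec(seed: int) -> ArchitectureSpec:
    """A randomly drawn, detectable architecture blueprint.

    LRR counts are drawn with modes at 5 and 21, mirroring the bimodal
    repeat-count distribution of real receptor cohorts; islands (when drawn)
    are at least two LRR units long so the gap detector can see them.
    """
    rng = np.random.default_rng(seed)
    mode = rng.choice([5, 21], p=[0.5, 0.5])
    n_lrr = max(1, int(rng.normal(mode, 1.5)))
    islands = []
    if n_lrr >= 10 and rng.random() < 0.4:
        idx = int(rng.integers(2, n_lrr - 2))
        islands.append((idx, int(rng.integers(48, 121))))
    return ArchitectureSpec(
        n_lrr=n_lrr,
        islands=islands,
        cys_pair_n=bool(rng.random() < 0.7),
        cys_pair_c=bool(rng.random() < 0.6),
        has_gdpc=bool(rng.random() < 0.3),
    )


# -- branch-site test records ----------------------------------------------


@dataclass
class BranchTestTruth:
    """Ground truth for one simulated branch-site test."""

    branch_id: str
    has_selection: bool = False
    ncp: float = 0.0
    true_sites: tuple[int, ...] = ()
    partition: DomainPartition = DomainPartition((("ECD", 300), ("ICD", 300)))
    np0: int = 203
    baseline_lnl: float = -50000.0

    def validate(self) -> None:
        if self.ncp < 0:
            raise ValueError("noncentrality must be >= 0")
        if not self.has_selection and self.true_sites:
            raise ValueError("true sites require has_selection")
        if any(
            not 0 <= s < self.partition.total for s in self.true_sites
        ):
            raise ValueError("true site positions outside the alignment")


def simulate_branch_test(
    truth: BranchTestTruth,
    seed: int,
    high_posterior: tuple[float, float] = (0.96, 1.0),
    low_posterior: tuple[float, float] = (0.0, 0.90),
) -> BranchTestResult:
    """Draw one branch-test record with known ground truth.

    The LRT statistic 2*(lnL1 - lnL0) is sampled from a central chi-square
    (df=1) without selection and a noncentral chi-square (df=1, the stated
    noncentrality) with; BEB posteriors are drawn from ``high_posterior`` at
    true sites and ``low_posterior`` elsewhere.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    if truth.has_selection and truth.ncp > 0:
        stat = float(rng.noncentral_chisquare(1.0, truth.ncp))
    else:
        stat = float(rng.chisquare(1.0))
    lnl0 = truth.baseline_lnl + float(rng.normal(0.0, 10.0))
    lnl1 = lnl0 + stat / 2.0
    true_set = set(truth.true_sites)
    sites = [
        SiteRecord(
            position=i,
            posterior=float(
                rng.uniform(*high_posterior)
                if i in true_set
                else rng.uniform(*low_posterior)
            ),
        )
        for i in range(truth.partition.total)
    ]
    return BranchTestResult(
        branch_id=truth.branch_id,
        np0=truth.np0,
        lnl0=lnl0,
        np1=truth.np0 + 1,
        lnl1=lnl1,
        sites=sites,
    )


# -- fixture output --------------------------------------------------------


def write_fixture_bundle(outputs: dict, directory) -> list[Path]:
    """Write simulated data plus the packaged printed-table fixtures.

    ``outputs`` may carry any of: ``proteins`` (list of (id, sequence)),
    ``trees`` (list of (name, root Node)), ``tables`` (dict name ->
    DataFrame), ``branch_tests`` (list of BranchTestResult). The packaged
    per-SG OG-count table and the 24-row branch-test table are always
    written alongside, so a fixture directory is self-contained.
    """
    from .datasets import load_branch_tests, load_og_counts

    directory = Path(directory)
    written: list[Path] = []

    def _write(path: Path, writer) -> None:
        try:
            writer(path)
        except OSError as exc:
            raise OSError(f"failed writing fixture {path}: {exc}") from exc
        written.append(path)

    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "proteins.fasta"
    records = outputs.get("proteins", [])
    _write(
        fasta,
        lambda p: p.write_text(
            "".join(f">{name}\n{seq}\n" for name, seq in records)
        ),
    )
    for name, root in outputs.get("trees", []):
        _write(
            directory / f"{name}.nwk",
            lambda p, r=root: p.write_text(write_newick(r) + "\n"),
        )
    for name, df in outputs.get("tables", {}).items():
        _write(
            directory / f"{name}.tsv",
            lambda p, d=df: d.to_csv(p, sep="\t", index=False),
        )
    branch_rows = [
        {
            "branch": r.branch_id,
            "np0": r.np0,
            "lnl0": r.lnl0,
            "np1": r.np1,
            "lnl1": r.lnl1,
        }
        for r in outputs.get("branch_tests", [])
    ]
    _write(
        directory / "branch_tests.tsv",
        lambda p: pd.DataFrame(
            branch_rows, columns=["branch", "np0", "lnl0", "np1", "lnl1"]
        ).to_csv(p, sep="\t", index=False),
    )
    _write(
        directory / "table1.tsv",
        lambda p: load_og_counts().to_csv(p, sep="\t", index=False),
    )
    _write(
        directory / "table2.tsv",
        lambda p: load_branch_tests().to_csv(p, sep="\t", index=False),
    )
    return written
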