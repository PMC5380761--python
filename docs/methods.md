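# Methods

This note documents the models, parameter choices and numerical conventions
behind `corekit`, and what the synthetic benchmarks do and do not show.

## Gene-family birth–death simulation

Families evolve along a rooted, binary species tree. One gene copy enters
the root; on every species-tree edge each extant copy experiences
duplication (rate λ) and loss (rate μ) events with exponential waiting
times, and at every speciation node each surviving copy bifurcates into the
two daughter edges. Lineages whose descendants all die are pruned, so the
returned gene tree contains only observable nodes; every surviving internal
node carries its true event label (speciation/duplication) and its species-
tree origin, and raw loss events are tallied per species-tree edge.

Parameters (per copy, per unit branch length; all edges of the packaged
species tree have length 1):

| parameter | default | rationale |
|---|---|---|
| duplication rate λ | 0.10 | gives cohorts of tens to ~150 genes per family on the 33-taxon tree, the size range of real LRR-RLK subgroup trees |
| loss rate μ | 0.05 | losses frequent but not dominating; the real family's rates are unknown, so defaults are illustrative |
| per-clade multipliers | none | optional lineage-specific expansion/contraction |
| forced root duplications | 0 | deterministic pre-root duplications for constructing known ancient-paralog histories |

True MD OG memberships are derived from the history: every surviving
speciation at the monocot/dicot crown node whose subtree retains ≥ 3
monocot and ≥ 4 dicot species defines one true OG.

Branch supports are attached separately: 1.0 everywhere under zero noise,
optionally degraded by |N(0, σ)| (clipped to [0, 1]), with per-node exact
overrides (keyed by leaf set) for placing targeted low supports. Every
generator is a pure function of (inputs, seed); one seeded NumPy generator
per call, no global state.

## Receptor sequence assembly and annotation

Sequences are assembled N→C as SP – [MLD] – GDPC/Cys-pair – LRR block
(islands inserted at stated indices) – Cys-pair – [MLD] – TM – KD, with all
true coordinates recorded as 0-based half-open intervals (converters only
at I/O boundaries).

The LRR unit is the 24-position consensus `LxxLxxLxLxxNxLSGxIPxxLxx`:
11 canonical positions (the letters) and 13 free positions (`x`). Free
positions, linkers, islands and the MLD placeholder draw from
`ADEHKQRT` — hydrophilic residues disjoint from the canonical alphabet and
from Cys — which guarantees that no shifted or random window can reach the
acceptance threshold (empirically the best off-phase window scores 3 of
11). SP and TM are hydrophobic stretches over `LIVFA` (21 and 23 residues);
the KD placeholder embeds the kinase hallmarks (Gly-rich loop, HRD, DFG).

Annotation is the inverse map:

* **LRR scan** — greedy left-to-right selection of non-overlapping
  24-residue windows scoring ≥ 9 of 11 canonical matches (position-weight
  matrix, ties to the leftmost start). This is a deterministic surrogate
  for a profile-HMM search; the exact Pfam score cutoffs used with real
  data are not recoverable, and the 9/11 threshold tolerates two canonical
  mutations per unit.
* **Islands** — inter-LRR gaps ≥ 48 residues (two LRR units), reported
  with LRR-equivalents = ⌊length/24⌋. The threshold is chosen so the
  smallest islands of biological interest — those spanning two repeats,
  e.g. a ~60-residue island (2 equivalents) — are detected. Shorter
  inter-repeat spacers are treated as linkers.
* **Cys pairs** — two Cys at most 8 residues apart, searched between the
  SP end and the first LRR (N-side) and between the last LRR and the TM
  (C-side); 8 covers the CxC to CxxxxxxC spacings described in receptors
  of this family. The GDPC cleavage motif is a literal substring search;
  its Cys may double as the first Cys of the N-side pair.
* **SP/TM** — Kyte–Doolittle sliding window (19 residues, mean ≥ 1.6),
  qualifying windows merged; a segment starting before residue 40 is the
  SP, later segments TM. These are standard surrogate values for dedicated
  topology predictors; all are configurable.
* **MLD** — presence/placement is an annotation flag, not a sequence scan:
  malectin detection in real data needs curated profile models, which are
  out of scope here.

The structural-class label is a total function evaluated as a decision
list (No_LRR → MLD placement → island size class → repeat-count bucket
with Cys-pair suffix); buckets are small ≤ 8, large ≥ 15, mid otherwise,
putting SERK-like co-receptors (4–5 LRRs, both Cys pairs) in
`LRR-small-cys-NC` and BRI1-like island receptors in `LRR-island-3plus`.

## Reconciliation and duplication-loss rooting

The classic parsimony LCA reconciliation: leaves map to their species
(species code = leaf-label prefix before the first underscore), internal
nodes to the LCA of their children's images; a node is a duplication iff
its image equals a child's image; losses on a gene-tree edge are the
species branches forking off the path between the two images (one fewer
under a speciation). Multifurcations are rejected rather than silently
resolved — simulated inputs are binary, and silent resolution would hide
upstream errors.

Unrooted trees are rooted by evaluating every edge of the unrooted topology
as a candidate root and keeping the minimum of D + L (equal weights — the
reference heuristic's exact weighting is unpublished, and equal weights
reproduce its reported behaviour). Ties break by smaller D, then by the
lexicographically smallest sorted leaf list of the root's first child, so
results are stable across runs and input leaf orderings. Outgroup leaves
participate like any other species; rooting works without them, which is
the point of rooting by reconciliation cost. The test suite checks the
minimum against an independent exhaustive enumeration (dendropy re-rooting)
on hundreds of random trees up to 12 leaves.

## MD ortholog groups

An MD OG root is an internal node with support strictly > 0.85 whose two
children split the subtree's leaves into an all-monocot and an all-dicot
set, with ≥ 3 monocot and ≥ 4 dicot species below and no outgroup leaf
inside (outgroup genes attached just outside the root do not disqualify
it). The species minima guard against clusters of misannotated sequences.

"Complex" OGs — clades whose duplication structure tracks the species tree
so poorly that no clean monocot/dicot bifurcation exists — are
operationalised as the *maximal* nodes meeting the support and species-count
conditions with monocot and dicot leaves intermingled below and no clean
qualifying bifurcation anywhere beneath them. Maximality prevents nested
double counting; reported OGs are pairwise leaf-disjoint by construction.

Simple-vs-complex classification of a clean OG counts duplication nodes
inside it whose species image is an *internal* species node; duplications
mapping to terminal species (paralogs after the monocot/dicot divergence
within one species) are ignored, and ≥ 2 such ancestral duplications make
the OG complex. The qualitative notion of "disorderly" duplication
structure has no unique formalisation; this surrogate is configurable and
validated against ground-truth event labels on simulations.

Census arithmetic rounds half-up to one decimal, matching printed-table
precision. Two printed values differ from their recomputation at the last
digit (3783/77 = 49.1 vs a printed 49.2; 14/101 = 13.9% vs a printed
13.8%); the summariser reports the computed values.

## Branch-site test post-processing

The LRT statistic is `max(0, 2(lnL_A − lnL_A0))` referred to the upper tail
of χ²(df = 1) — the alternative has exactly one extra parameter, and the
plain χ²(1) null (not the 50:50 boundary mixture sometimes used for
branch-site tests) reproduces all 24 printed p-values, so it is the
distribution actually used for the reference numbers. Negative statistics
(optimiser noise in the source fits) are clamped to 0 rather than rejected.

Significance coding is two-tier Bonferroni over n = 24 tested branches:
`**` below 0.01/24, `*` below 0.05/24, `ns` otherwise. Only the 0.05/24
threshold is stated in the source; the 0.01/24 second tier is the unique
simple scheme consistent with all 24 printed codes and is configurable.

BEB site filtering keeps posteriors strictly above 0.95 (a posterior of
exactly 0.95 fails). Sites map to domains by interval lookup over the
annotated architecture; ECD aggregates everything N-terminal of the TM
start, ICD everything C-terminal of the TM end, and TM sites belong to
neither — consistent with reference rows where ECD + ICD < total.
Within-LRR phase is (position − unit start) mod 24, canonical iff the
phase is one of the 11 canonical positions (expected canonical fraction
for uniform sites: 11/24 ≈ 0.458). Domain-density comparisons are
goodness-of-fit χ² with expectations proportional to domain lengths.

The branch-test simulator draws the LRT statistic directly from its
sampling distribution (central χ²(1) without selection, noncentral with
the stated noncentrality) instead of simulating codon evolution: the
component under test is the post-processing, not the likelihood optimiser.

## What the synthetic benchmarks do and do not show

The generators reproduce the *structure* of the real analysis — known
duplication/loss histories, exact domain coordinates, calibrated null
statistics — so tests can demand exact recovery (precision = recall = 1 on
loss-free families; exact blueprint round-trips). They do not emulate
alignment error, trimming artefacts, support-value miscalibration beyond
simple noise, profile-HMM score distributions, degenerate repeat units, or
annotation errors in real proteomes. Passing these benchmarks therefore
shows the pipeline's logic is correct under its stated model, not that the
upstream tools it consumes are error-free. Family-wide discovery numbers
(e.g. the identity of the 101 OGs in 33 real proteomes) require the real
data and are covered only by the printed-table arithmetic.

## Problem sizes

The shipped analyses use cohorts chosen for the repository's scale: 50–100
simulated families on the 33-taxon tree, 100–200 random trees (≤ 12
leaves) for the rooting oracle, 100–200 receptor blueprints, 5000
replicates for the null-calibration checks and 4000 sites for the
canonical-fraction check. All are configurable at the call site.
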