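"""Extracellular-domain architecture annotation for LRR-RLK proteins.

An LRR-RLK receptor is built, N- to C-terminus, from a signal peptide (SP),
an optional malectin-like domain (MLD), a cysteine pair, a block of
leucine-rich repeats (LRRs, 24-residue units) possibly interrupted by island
domains, a second cysteine pair, a transmembrane helix (TM) and an
intracellular kinase domain (KD). This module locates those elements in a
plain amino-acid sequence and assigns a structural-class label.

The LRR unit is modelled as a 24-position consensus with 11 canonical
(conserved) and 13 non-canonical (free) positions; a sliding window is
accepted as an LRR when at least 9 of the 11 canonical positions match. The
scan is a deterministic, transparent surrogate for a profile-HMM search:
greedy left-to-right selection of non-overlapping qualifying windows.
SP/TM segments are found with a Kyte–Doolittle hydropathy window, a standard
surrogate for dedicated topology predictors. MLD presence is an annotation
flag, not a sequence scan.

All coordinates are 0-based, half-open residue intervals.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from math import floor
from typing import Optional, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "LRR_TEMPLATE",
    "LRRMotifSpec",
    "MotifHit",
    "Island",
    "DomainArchitecture",
    "scan_lrr",
    "detect_islands",
    "detect_gdpc",
    "detect_cys_pairs",
    "detect_hydrophobic_segments",
    "annotate",
    "classify_architecture",
    "lrr_count_histogram",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 24-position LRR consensus; lowercase ``x`` marks the 13 non-canonical
#: (free) positions, letters the 11 canonical ones.
LRR_TEMPLATE = "LxxLxxLxLxxNxLSGxIPxxLxx"


@dataclass(frozen=True)
class LRRMotifSpec:
    """Position-weight description of the LRR unit.

    ``weights[i]`` maps residues to their score contribution at template
    position ``i``; the default gives 1.0 to the consensus residue at each
    canonical position and nothing elsewhere, so the score of a window is
    simply its number of canonical matches (0..11).
    """

    template: str = LRR_TEMPLATE
    threshold: float = 9.0
    weights: Optional[tuple[dict[str, float], ...]] = None

    def __post_init__(self):
        if self.weights is None:
            object.__setattr__(
                self,
                "weights",
                tuple(
                    {c: 1.0} if c != "x" else {} for c in self.template
                ),
            )
        if len(self.weights) != len(self.template):
            raise ValueError("weights must cover every template position")

    @property
    def length(self) -> int:
        return len(self.template)

    @property
    def canonical_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.template) if c != "x")

    @property
    def non_canonical_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.template) if c == "x")

    def score(self, window: str) -> float:
        return sum(
            self.weights[i].get(res, 0.0) for i, res in enumerate(window)
        )


@dataclass(frozen=True, order=True)
class MotifHit:
    """One located sequence element, as a 0-based half-open interval."""

    start: int
    end: int
    kind: str = field(compare=False)
    score: float = field(default=0.0, compare=False)

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Island:
    """A non-LRR stretch lying strictly between two LRR hits."""

    start: int
    end: int
    left_lrr_index: int
    right_lrr_index: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def lrr_equivalents(self) -> int:
        return floor(self.length / 24)


@dataclass
class DomainArchitecture:
    """Full ordered domain layout of one protein."""

    sequence_length: int
    hits: list[MotifHit] = field(default_factory=list)
    islands: list[Island] = field(default_factory=list)
    has_sp: bool = False
    has_tm: bool = False
    has_kd: bool = False
    has_mld: bool = False
    mld_placement: Optional[str] = None  # "N" or "preTM"
    cys_pair_n: bool = False
    cys_pair_c: bool = False
    gdpc_positions: list[int] = field(default_factory=list)

    @property
    def lrr_hits(self) -> list[MotifHit]:
        return [h for h in self.hits if h.kind == "LRR"]

    @property
    def n_lrr(self) -> int:
        return len(self.lrr_hits)

    def hit(self, kind: str) -> Optional[MotifHit]:
        for h in self.hits:
            if h.kind == kind:
                return h
        return None


# -- scanners --------------------------------------------------------------


def _check_alphabet(sequence: str) -> None:
    for i, res in enumerate(sequence):
        if res not in AMINO_ACIDS and res != "X":
            raise ValueError(
                f"illegal character {res!r} at position {i} of sequence"
            )


def scan_lrr(
    sequence: str, spec: LRRMotifSpec = LRRMotifSpec()
) -> list[MotifHit]:
    """Greedy non-overlapping LRR scan.

    Windows of the template length whose position-weight score reaches
    ``spec.threshold`` are accepted left to right; an accepted window blocks
    every window overlapping it, which resolves ties in favour of the
    leftmost start. ``X`` residues score 0 wherever they fall.
    """
    _check_alphabet(sequence)
    hits: list[MotifHit] = []
    i, L = 0, spec.length
    while i + L <= len(sequence):
        s = spec.score(sequence[i : i + L])
        if s >= spec.threshold:
            hits.append(MotifHit(i, i + L, "LRR", s))
            i += L
        else:
            i += 1
    return hits


def detect_islands(
    hits: Sequence[MotifHit], min_gap: int = 48
) -> list[Island]:
    """Inter-LRR gaps of at least ``min_gap`` residues, as islands.

    The default of 48 residues (two LRR units) makes the smallest islands of
    interest — those spanning two repeats — detectable.
    """
    for a, b in zip(hits, hits[1:]):
        if b.start < a.end:
            raise ValueError("LRR hits must be sorted and non-overlapping")
    islands = []
    for idx, (a, b) in enumerate(zip(hits, hits[1:])):
        gap = b.start - a.end
        if gap >= min_gap:
            islands.append(Island(a.end, b.start, idx, idx + 1))
    return islands


def detect_gdpc(
    sequence: str, region: Optional[tuple[int, int]] = None
) -> list[int]:
    """Start positions of every literal ``GDPC`` in ``region`` (whole
    sequence by default)."""
    start, end = region if region is not None else (0, len(sequence))
    if not 0 <= start <= end <= len(sequence):
        raise ValueError(f"region [{start}, {end}) outside sequence")
    return [
        m.start() + start
        for m in re.finditer("(?=GDPC)", sequence[start:end])
    ]


def _has_cys_pair(segment: str, offset_window: int) -> bool:
    cys = [i for i, r in enumerate(segment) if r == "C"]
    return any(b - a <= offset_window for a, b in zip(cys, cys[1:]))


def detect_cys_pairs(
    sequence: str,
    arch: DomainArchitecture,
    pair_window: int = 8,
) -> tuple[bool, bool]:
    """Presence of the N-side and C-side cysteine pairs flanking the LRRs.

    The N-side pair is searched between the SP end (or position 0) and the
    first LRR; the C-side pair between the last LRR and the TM start (or the
    sequence end). A pair is two Cys at most ``pair_window`` residues apart.
    """
    if pair_window < 2:
        raise ValueError("pair_window must be at least 2")
    lrrs = arch.lrr_hits
    if not lrrs:
        return (False, False)
    sp = arch.hit("SP")
    tm = arch.hit("TM")
    n_lo = sp.end if sp else 0
    n_region = sequence[n_lo : lrrs[0].start]
    c_region = sequence[lrrs[-1].end : tm.start if tm else len(sequence)]
    return (
        _has_cys_pair(n_region, pair_window),
        _has_cys_pair(c_region, pair_window),
    )


def detect_hydrophobic_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    sp_cutoff: int = 40,
) -> list[MotifHit]:
    """SP/TM candidates from a Kyte–Doolittle hydropathy sliding window.

    Windows whose mean hydropathy reaches ``threshold`` are merged into
    segments; a segment starting within the first ``sp_cutoff`` residues is
    labelled SP, later ones TM.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    scores = [KYTE_DOOLITTLE.get(r, 0.0) for r in sequence]
    spans = []
    if n >= window:
        running = sum(scores[:window])
        for i in range(n - window + 1):
            if i:
                running += scores[i + window - 1] - scores[i - 1]
            if running / window >= threshold:
                spans.append((i, i + window))
    # merge overlapping qualifying windows
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    hits = []
    seen_sp = False
    for s, e in merged:
        mean = sum(scores[s:e]) / (e - s)
        kind = "SP" if (s < sp_cutoff and not seen_sp) else "TM"
        seen_sp = seen_sp or kind == "SP"
        hits.append(MotifHit(s, e, kind, mean))
    return hits


_KD_HALLMARKS = ("HRD", "DFG")


def annotate(
    sequence: str,
    lrr_spec: LRRMotifSpec = LRRMotifSpec(),
    min_gap: int = 48,
    pair_window: int = 8,
    has_mld: bool = False,
    mld_placement: Optional[str] = None,
) -> DomainArchitecture:
    """Full architecture annotation of one protein sequence.

    MLD presence/placement is taken from annotation flags (it is not scanned
    from sequence); everything else is inferred. KD presence requires both
    catalytic hallmark motifs (HRD, DFG) after the TM segment (or the last
    LRR when no TM is found).
    """
    _check_alphabet(sequence)
    hydro = detect_hydrophobic_segments(sequence)
    lrrs = scan_lrr(sequence, lrr_spec)
    # keep only the first SP and the first TM after the LRR block
    sp = next((h for h in hydro if h.kind == "SP"), None)
    lrr_end = lrrs[-1].end if lrrs else (sp.end if sp else 0)
    tm = next((h for h in hydro if h.kind == "TM" and h.start >= lrr_end), None)
    arch = DomainArchitecture(
        sequence_length=len(sequence),
        has_sp=sp is not None,
        has_tm=tm is not None,
        has_mld=has_mld,
        mld_placement=mld_placement if has_mld else None,
    )
    arch.hits = sorted(
        ([sp] if sp else []) + ([tm] if tm else []) + lrrs
    )
    arch.islands = detect_islands(lrrs, min_gap=min_gap)
    arch.cys_pair_n, arch.cys_pair_c = detect_cys_pairs(
        sequence, arch, pair_window=pair_window
    )
    arch.gdpc_positions = detect_gdpc(
        sequence, (0, lrrs[0].start) if lrrs else None
    )
    icd_start = tm.end if tm else lrr_end
    tail = sequence[icd_start:]
    if all(motif in tail for motif in _KD_HALLMARKS):
        arch.has_kd = True
        kd_start = icd_start + tail.index("HRD")
        arch.hits.append(MotifHit(kd_start, len(sequence), "KD"))
        arch.hits.sort()
    return arch


# -- classification --------------------------------------------------------


def classify_architecture(arch: DomainArchitecture) -> str:
    """Deterministic structural-class label.

    Decision list, first match wins:

    1. ``No_LRR`` — no LRR motif (kinase homologue with lost/degenerate ECD).
    2. ``MLD-N-terminal`` — malectin-like domain after the SP (SYMRK-like).
    3. ``MLD-pre-TM`` — malectin-like domain between LRRs and TM.
    4. ``LRR-island-2`` / ``LRR-island-3plus`` — island-bearing receptors,
       by the largest island's LRR-equivalents (BRI1-like when >= 3).
    5. ``LRR-<bucket>[-cys-<sides>]`` — plain LRR receptors bucketed by
       repeat count (``small`` <= 8, ``large`` >= 15, ``mid`` otherwise),
       with flanking cysteine pairs appended as ``-cys-N``, ``-cys-C`` or
       ``-cys-NC`` (SERK co-receptors fall in ``LRR-small-cys-NC``).
    """
    if arch.n_lrr == 0:
        return "No_LRR"
    if arch.has_mld:
        return "MLD-N-terminal" if arch.mld_placement == "N" else "MLD-pre-TM"
    if arch.islands:
        big = max(i.lrr_equivalents for i in arch.islands)
        return "LRR-island-3plus" if big >= 3 else "LRR-island-2"
    if arch.n_lrr <= 8:
        bucket = "small"
    elif arch.n_lrr >= 15:
        bucket = "large"
    else:
        bucket = "mid"
    sides = ("N" if arch.cys_pair_n else "") + ("C" if arch.cys_pair_c else "")
    return f"LRR-{bucket}" + (f"-cys-{sides}" if sides else "")


def lrr_count_histogram(
    architectures: Sequence[DomainArchitecture],
) -> tuple[dict[int, int], list[int]]:
    """Histogram of LRR counts per protein, plus its mode(s)."""
    counts = Counter(a.n_lrr for a in architectures)
    if not counts:
        return {}, []
    top = max(counts.values())
    modes = sorted(k for k, v in counts.items() if v == top)
    return dict(sorted(counts.items())), modes
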