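"""Post-processing of branch-site positive-selection tests.

A branch-site test compares, for one foreground branch, a null model in which
no site may have dN/dS (omega) above 1 against an alternative allowing
positive selection at some sites on that branch. The comparison is a
likelihood-ratio test: 2*(lnL_alt - lnL_null) referred to a chi-square with
one degree of freedom (the alternative has exactly one extra parameter).
With many branches tested, significance thresholds are Bonferroni-corrected
by the number of tests; per-site evidence comes from Bayes empirical Bayes
(BEB) posterior probabilities of omega > 1, filtered at a strict cutoff.

Small numerical optimiser noise can leave the alternative log-likelihood
below the null; the statistic is clamped at 0 (p = 1) in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import chi2, chisquare

from .domain_architecture import DomainArchitecture, LRRMotifSpec, MotifHit

__all__ = [
    "BranchTestResult",
    "SiteRecord",
    "MultipleTestingScheme",
    "DomainPartition",
    "lrt_pvalue",
    "significance_code",
    "filter_beb_sites",
    "map_sites_to_domains",
    "lrr_phase_classify",
    "domain_density_test",
    "summarize_selection",
    "branch_results_from_table",
    "recompute_branch_table",
]

NOT_SIGNIFICANT = "ns"


@dataclass
class SiteRecord:
    """One codon position with its BEB posterior of omega > 1.

    Positions are 0-based internally; 1-based only at I/O boundaries.
    """

    position: int
    posterior: float
    domain: Optional[str] = None
    lrr_phase: Optional[int] = None
    canonical: Optional[bool] = None

    def __post_init__(self):
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")


@dataclass
class BranchTestResult:
    """Paired null/alternative model fit for one foreground branch."""

    branch_id: str
    np0: int
    lnl0: float
    np1: int
    lnl1: float
    sg: str = ""
    structural_sg: str = ""
    known_genes: str = ""
    pair_id: Optional[int] = None
    n_sites: Optional[int] = None
    ecd_sites: Optional[int] = None
    icd_sites: Optional[int] = None
    sites: list[SiteRecord] = field(default_factory=list)


@dataclass(frozen=True)
class MultipleTestingScheme:
    """Bonferroni-corrected two-tier significance coding.

    ``**`` below alpha_strong / n_tests, ``*`` below alpha_weak / n_tests,
    ``ns`` otherwise.
    """

    alpha_weak: float = 0.05
    alpha_strong: float = 0.01
    n_tests: int = 24

    def __post_init__(self):
        if not 0 < self.alpha_strong < self.alpha_weak <= 1:
            raise ValueError("need 0 < alpha_strong < alpha_weak <= 1")
        if self.n_tests < 1:
            raise ValueError("n_tests must be positive")

    @property
    def weak_threshold(self) -> float:
        return self.alpha_weak / self.n_tests

    @property
    def strong_threshold(self) -> float:
        return self.alpha_strong / self.n_tests


@dataclass(frozen=True)
class DomainPartition:
    """Ordered (domain name, length in codons) partition of an alignment."""

    parts: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if any(length <= 0 for _, length in self.parts):
            raise ValueError("domain lengths must be positive")

    @property
    def total(self) -> int:
        return sum(length for _, length in self.parts)


def lrt_pvalue(result: BranchTestResult) -> tuple[float, float]:
    """LRT statistic and chi-square (df=1) upper-tail p-value."""
    if result.np1 != result.np0 + 1:
        raise ValueError(
            f"{result.branch_id}: expected np1 = np0 + 1, "
            f"got np0={result.np0}, np1={result.np1}"
        )
    if not (isfinite(result.lnl0) and isfinite(result.lnl1)):
        raise ValueError(f"{result.branch_id}: non-finite log-likelihood")
    stat = max(0.0, 2.0 * (result.lnl1 - result.lnl0))
    p = 1.0 if stat == 0.0 else float(chi2.sf(stat, df=1))
    return stat, p


def significance_code(
    p: float, scheme: MultipleTestingScheme = MultipleTestingScheme()
) -> str:
    """Two-tier Bonferroni code: ``**``, ``*`` or ``ns``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < scheme.strong_threshold:
        return "**"
    if p < scheme.weak_threshold:
        return "*"
    return NOT_SIGNIFICANT


def filter_beb_sites(
    sites: Sequence[SiteRecord], threshold: float = 0.95
) -> list[SiteRecord]:
    """Sites whose BEB posterior is strictly above ``threshold``."""
    return [s for s in sites if s.posterior > threshold]


def map_sites_to_domains(
    sites: Sequence[SiteRecord], arch: DomainArchitecture
) -> dict[str, int]:
    """Assign each site to exactly one domain by interval lookup.

    Returns per-domain counts plus ``ECD``/``ICD`` aggregates: ECD is
    everything N-terminal of the TM start, ICD everything C-terminal of the
    TM end; TM sites belong to neither aggregate. Site ``domain`` fields are
    filled in place.
    """
    tm = arch.hit("TM")
    lrr_end = arch.lrr_hits[-1].end if arch.lrr_hits else 0
    ecd_limit = tm.start if tm else lrr_end
    icd_start = tm.end if tm else lrr_end
    counts: dict[str, int] = {}
    ecd = icd = 0
    for site in sites:
        if not 0 <= site.position < arch.sequence_length:
            raise ValueError(
                f"site at position {site.position} outside protein of length "
                f"{arch.sequence_length}"
            )
        domain = None
        for h in arch.hits:
            if h.start <= site.position < h.end:
                domain = h.kind
                break
        if domain is None:
            for isl in arch.islands:
                if isl.start <= site.position < isl.end:
                    domain = "island"
                    break
        if domain is None:
            domain = "other-ECD" if site.position < icd_start else "other-ICD"
        site.domain = domain
        counts[domain] = counts.get(domain, 0) + 1
        if domain != "TM":
            if site.position < ecd_limit:
                ecd += 1
            elif site.position >= icd_start:
                icd += 1
    counts["ECD"] = ecd
    counts["ICD"] = icd
    return counts


def lrr_phase_classify(
    site: SiteRecord,
    lrr_hits: Sequence[MotifHit],
    spec: LRRMotifSpec = LRRMotifSpec(),
) -> tuple[int, bool]:
    """Phase of a site within its LRR unit and its canonical flag."""
    for h in lrr_hits:
        if h.start <= site.position < h.end:
            phase = (site.position - h.start) % spec.length
            canonical = phase in spec.canonical_positions
            site.lrr_phase, site.canonical = phase, canonical
            return phase, canonical
    raise ValueError(f"site at position {site.position} lies in no LRR hit")


def domain_density_test(
    counts: Sequence[int], partition: DomainPartition
) -> tuple[float, float]:
    """Goodness-of-fit chi-square of site counts against domain lengths.

    Expected counts are proportional to domain lengths; df = k - 1.
    """
    if len(counts) != len(partition.parts):
        raise ValueError("one count per domain required")
    if len(counts) < 2:
        raise ValueError("need at least two domains")
    total = sum(counts)
    if total == 0:
        raise ValueError("no sites to test")
    expected = [
        total * length / partition.total for _, length in partition.parts
    ]
    stat, p = chisquare(list(counts), f_exp=expected)
    return float(stat), float(p)


def summarize_selection(
    results: Sequence[BranchTestResult],
    scheme: MultipleTestingScheme = MultipleTestingScheme(),
) -> dict:
    """Totals over a set of branch tests.

    Reports the summed validated-site count, branches per significance code,
    and — for branches grouped into ancestral-duplication pairs via
    ``pair_id`` — how many pairs show selection on neither, one, or both
    branches.
    """
    codes: dict[str, int] = {"ns": 0, "*": 0, "**": 0}
    total_sites = 0
    ecd_total = icd_total = 0
    by_pair: dict[int, list[str]] = {}
    for res in results:
        _, p = lrt_pvalue(res)
        code = significance_code(p, scheme)
        codes[code] += 1
        total_sites += res.n_sites or 0
        ecd_total += res.ecd_sites or 0
        icd_total += res.icd_sites or 0
        if res.pair_id is not None:
            by_pair.setdefault(res.pair_id, []).append(code)
    pairs = {"no_signal": 0, "one_branch": 0, "both_branch": 0}
    for members in by_pair.values():
        n_sig = sum(1 for c in members if c != NOT_SIGNIFICANT)
        if n_sig == 0:
            pairs["no_signal"] += 1
        elif n_sig == len(members):
            pairs["both_branch"] += 1
        else:
            pairs["one_branch"] += 1
    return {
        "n_branches": len(results),
        "total_sites": total_sites,
        "ecd_sites": ecd_total,
        "icd_sites": icd_total,
        "codes": codes,
        "pairs": pairs,
    }


# -- table I/O -------------------------------------------------------------


def branch_results_from_table(df: pd.DataFrame) -> list[BranchTestResult]:
    """Build :class:`BranchTestResult` rows from a branch-table DataFrame.

    Expects columns ``branch``, ``np0``, ``lnl0``, ``np1``, ``lnl1`` and
    passes through the optional descriptive/site-count columns.
    """

    def _opt_int(row, col):
        val = getattr(row, col, None)
        return None if val is None or pd.isna(val) else int(val)

    results = []
    for row in df.itertuples():
        results.append(
            BranchTestResult(
                branch_id=row.branch,
                np0=int(row.np0),
                lnl0=float(row.lnl0),
                np1=int(row.np1),
                lnl1=float(row.lnl1),
                sg=getattr(row, "sg", ""),
                structural_sg=getattr(row, "structural_sg", ""),
                known_genes=getattr(row, "known_genes", ""),
                pair_id=_opt_int(row, "pair_id"),
                n_sites=_opt_int(row, "n_sites"),
                ecd_sites=_opt_int(row, "ecd_sites"),
                icd_sites=_opt_int(row, "icd_sites"),
            )
        )
    return results


def recompute_branch_table(
    results: Sequence[BranchTestResult],
    scheme: MultipleTestingScheme = MultipleTestingScheme(),
) -> pd.DataFrame:
    """LRT statistic, p-value and significance code for every branch."""
    rows = []
    for res in results:
        stat, p = lrt_pvalue(res)
        rows.append(
            {
                "branch": res.branch_id,
                "sg": res.sg,
                "pair_id": res.pair_id,
                "np0": res.np0,
                "lnl0": res.lnl0,
                "np1": res.np1,
                "lnl1": res.lnl1,
                "lrt_stat": stat,
                "p_value": p,
                "code": significance_code(p, scheme),
                "n_sites": res.n_sites,
                "ecd_sites": res.ecd_sites,
                "icd_sites": res.icd_sites,
            }
        )
    return pd.DataFrame(rows)
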