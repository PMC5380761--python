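"""Loaders for the small packaged data tables.

Two printed summary tables travel with the package as TSV fixtures:

* ``table1_og_counts.tsv`` — number of monocot/dicot ortholog groups (MD OGs)
  and of complex OGs per subgroup (SG) of the LRR-RLK kinase-domain phylogeny.
* ``table2_branch_tests.tsv`` — the 24 branch-site test rows (12 OG pairs):
  paired null/alternative log-likelihoods, parameter counts, printed p-values
  and significance codes, and validated site counts split into ECD/ICD.

They are inputs to the summary arithmetic, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_og_counts", "load_branch_tests"]

_SITE_COLS = ["n_sites", "ecd_sites", "icd_sites"]


def load_og_counts() -> pd.DataFrame:
    """Per-SG MD OG counts: columns ``sg``, ``n_md_og``, ``n_og_c``."""
    path = resources.files("corekit.data") / "table1_og_counts.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_branch_tests() -> pd.DataFrame:
    """The 24 branch-site test rows.

    Site-count columns are nullable integers; a missing ``n_sites`` means the
    branch was not significant and no sites were evaluated (printed "-").
    """
    path = resources.files("corekit.data") / "table2_branch_tests.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(
            p, sep="\t", dtype={"known_genes": str, "printed_p": str}
        )
    for col in _SITE_COLS:
        df[col] = df[col].astype("Int64")
    df["known_genes"] = df["known_genes"].fillna("")
    df["structural_sg"] = df["structural_sg"].fillna("")
    return df
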