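#!/usr/bin/env python
"""Annotate a synthetic receptor cohort and profile its LRR counts.

Simulates a cohort of receptors with blueprints drawn around the two
repeat-count peaks seen in real LRR-RLK sets (about 5 and about 21 LRRs),
annotates every sequence from scratch, verifies the blueprint round-trip,
and writes the per-protein architecture table and the LRR-count histogram.
"""

import argparse
from pathlib import Path

import pandas as pd

from corekit.domain_architecture import (
    annotate,
    classify_architecture,
    lrr_count_histogram,
)
from corekit.synthetic_data import random_architecture_spec, simulate_protein

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-proteins", type=int, default=200)
    args = parser.parse_args()

    rows, archs = [], []
    exact = 0
    for i in range(args.n_proteins):
        spec = random_architecture_spec(args.seed * 100 + i)
        seq, truth = simulate_protein(spec, seed=args.seed * 100 + i + 7)
        arch = annotate(seq)
        archs.append(arch)
        exact += arch.n_lrr == truth.n_lrr and len(arch.islands) == len(
            truth.islands
        )
        rows.append(
            {
                "id": f"prot{i:03d}",
                "length": arch.sequence_length,
                "n_lrr": arch.n_lrr,
                "islands": ";".join(
                    f"{isl.start}-{isl.end}" for isl in arch.islands
                ),
                "cys_pair_n": arch.cys_pair_n,
                "cys_pair_c": arch.cys_pair_c,
                "n_gdpc": len(arch.gdpc_positions),
                "class": classify_architecture(arch),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(BASE / "architectures.tsv", sep="\t", index=False)
    hist, modes = lrr_count_histogram(archs)
    pd.DataFrame(
        {"n_lrr": list(hist), "n_proteins": list(hist.values())}
    ).to_csv(BASE / "lrr_histogram.tsv", sep="\t", index=False)
    print(
        f"annotated {len(table)} receptors; blueprint round-trip exact for "
        f"{exact}/{args.n_proteins}; histogram modes {modes}"
    )
    print(table["class"].value_counts().to_string())


if __name__ == "__main__":
    main()
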