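"""Call ecDNA+ cells from the simulated fragments and score against truth.

Reads data/fragments (from 01_simulate_inputs.py), applies cell QC, runs the
Monte Carlo permutation caller and writes per-cell calls, the co-occurrence
summary and a small truth-scored table under --out.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ecdna.caller import (
    PermutationConfig,
    apply_cell_qc,
    call_cells,
    qc_stats_from_frame,
)
from ecdna.genome import FragmentIndex, RegionSet, read_bed_grouped, read_chrom_sizes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-perm", type=int, default=1_000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    frag_dir = args.data / "fragments"
    genome = read_chrom_sizes(frag_dir / "chrom.sizes")
    amplicons = read_bed_grouped(frag_dir / "amplicons.bed")
    qc = pd.read_csv(frag_dir / "qc.tsv", sep="\t")
    barcodes = apply_cell_qc(qc_stats_from_frame(qc))
    print(f"cell QC retained {len(barcodes)}/{len(qc)} barcodes")

    index = FragmentIndex.from_file(frag_dir / "fragments.tsv", barcodes)
    calls, summary = call_cells(
        index,
        amplicons,
        RegionSet("exclusions", ()),
        genome,
        PermutationConfig(n_permutations=args.n_perm, seed=args.seed),
    )

    args.out.mkdir(parents=True, exist_ok=True)
    calls.to_csv(args.out / "cell_calls.tsv", sep="\t", index=False)
    (args.out / "call_summary.json").write_text(
        json.dumps(
            {"co_occurrence": summary.counts, "total_cells": summary.total_cells},
            indent=2,
        )
    )

    truth = pd.read_csv(frag_dir / "truth" / "copy_number.tsv", sep="\t")
    merged = calls.merge(truth, on=["barcode", "amplicon"])
    strong = merged[merged.copy_number >= 10]
    called = merged[merged.called]
    scores = {
        "sensitivity_cn10": float(strong.called.mean()),
        "fdr": float((called.copy_number == 2).mean()) if len(called) else 0.0,
        "n_strong": int(len(strong)),
        "n_called": int(len(called)),
    }
    (args.out / "call_scores.json").write_text(json.dumps(scores, indent=2))
    print(json.dumps(scores, indent=2))
    print(f"co-occurrence: {summary.counts}")


if __name__ == "__main__":
    main()
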