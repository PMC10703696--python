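"""Fingerprint the simulated WGS cohort and flag same-patient duplicates.

Reads data/fingerprints (from 01_simulate_inputs.py), computes pairwise
VAF correlations, writes the correlation matrix and flagged pairs, and
scores the flags against the known patient assignment.
"""

import argparse
import itertools
import json
from pathlib import Path

import pandas as pd

from ecdna.fingerprint import pairwise_fingerprint, read_counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--r-threshold", type=float, default=0.80)
    args = parser.parse_args()

    d = args.data / "fingerprints"
    samples = read_counts(d / "counts.tsv")
    result = pairwise_fingerprint(samples, threshold=args.r_threshold)

    args.out.mkdir(parents=True, exist_ok=True)
    result.correlation.to_csv(args.out / "fingerprint_correlation.tsv", sep="\t")

    truth = pd.read_csv(d / "truth" / "patients.tsv", sep="\t")
    patient = dict(zip(truth["sample"], truth.patient))
    truth_pairs = {
        tuple(sorted((a, b)))
        for a, b in itertools.combinations(result.sample_ids, 2)
        if patient[a] == patient[b]
    }
    flagged = {tuple(sorted(p)) for p in result.duplicate_pairs}
    payload = {
        "duplicate_pairs": sorted(flagged),
        "truth_pairs": sorted(truth_pairs),
        "all_correct": flagged == truth_pairs,
        "indeterminate_pairs": result.indeterminate_pairs,
        "threshold": result.threshold,
    }
    (args.out / "fingerprint_duplicates.json").write_text(
        json.dumps(payload, indent=2)
    )
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
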