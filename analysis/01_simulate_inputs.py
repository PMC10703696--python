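"""Generate all synthetic inputs with ground truth for the analysis chain.

Writes four datasets under --data: snATAC fragments (fragments/), FISH
fields (fish/clean, fish/noisy), a fingerprint cohort (fingerprints/) and a
survival cohort (cohort/). Downstream drivers 02-05 read from the same
--data directory.
"""

import argparse
import json
from pathlib import Path

from ecdna.simulate import (
    CohortSimConfig,
    FingerprintSimConfig,
    FishSimConfig,
    FragmentSimConfig,
    gen_cohort,
    gen_fingerprints,
    gen_fish_image,
    gen_fragments,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("data"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--n-cells", type=int, default=2_000, help="snATAC cells to simulate"
    )
    args = parser.parse_args()

    gen_fragments(FragmentSimConfig(n_cells=args.n_cells, seed=args.seed)).write(
        args.data / "fragments"
    )
    print(f"fragments -> {args.data / 'fragments'}")

    gen_fish_image(FishSimConfig(seed=args.seed)).write(args.data / "fish" / "clean")
    gen_fish_image(FishSimConfig(seed=args.seed + 1, noise_sd=5.0)).write(
        args.data / "fish" / "noisy"
    )
    print(f"FISH fields -> {args.data / 'fish'}")

    gen_fingerprints(FingerprintSimConfig(seed=args.seed)).write(
        args.data / "fingerprints"
    )
    print(f"fingerprint cohort -> {args.data / 'fingerprints'}")

    frame, truth = gen_cohort(CohortSimConfig(seed=args.seed))
    outdir = args.data / "cohort"
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "truth" / "parameters.json").write_text(
        json.dumps(truth, indent=2, default=float)
    )
    print(f"survival cohort -> {outdir}")


if __name__ == "__main__":
    main()
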