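#!/usr/bin/env python
"""Monte-Carlo demonstration that oblique crushing inflates the metrics.

Generates smooth, gently trending synthetic columns (the shape mechanics
would produce in an undistorted neck), crushes each vertebra independently
at a random angle under area-preserving plastic flow, and compares the
serial-variation metrics of the crushed and uncrushed columns across
replicates.  Writes the per-replicate table to results/.
"""

import argparse
from pathlib import Path

from neckmetrics import CrushIntensity, TrueColumnModel, discrimination_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=200)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    model = TrueColumnModel(n=14, vh_start=0.85, vh_end=0.90, noise_sd=0.01,
                            seed=args.seed)
    intensity = CrushIntensity(k_min=0.7, k_max=1.0, gamma=1.0, seed=args.seed)
    result = discrimination_experiment(model, intensity, args.replicates)
    result.table.to_csv(RESULTS / "crush_discrimination.csv", index=False)

    t = result.table
    print(
        f"{args.replicates} replicates, n=14 vertebrae, V/H 0.85->0.90, "
        f"k ~ U(0.7, 1.0), gamma = 1 (area-preserving)\n"
        f"mean difference metric: uncrushed {t['uncrushed_diff_x100'].mean():.2f}, "
        f"crushed {t['crushed_diff_x100'].mean():.2f}\n"
        f"crushed exceeds uncrushed in {result.exceed_fraction_diff:.1%} "
        f"(difference metric) and {result.exceed_fraction_ratio:.1%} (ratio metric) "
        "of replicates"
    )


if __name__ == "__main__":
    main()
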