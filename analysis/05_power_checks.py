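"""Post hoc empirical power of the group comparisons.

For each direction (worsened / improved, from the final MCID
classification) and each anchor scale, estimates by Monte-Carlo
resampling the power of the two-sided Mann-Whitney U test comparing the
direction group's anchor changes against everyone else's.

Outputs: results/power.json
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from facit_mcid.mcid_estimation import DEFAULT_ANCHORS, DIRECTIONS, oriented_delta
from facit_mcid.power_simulation import PowerSpec, resampler, wmw_power
from facit_mcid.synthetic_cohort import read_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=20260925)
    parser.add_argument("--n-reps", type=int, default=5000)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.cohort)
    labels = pd.read_csv(args.labels)
    merged = cohort.merge(labels, on="patient_id")

    out = {}
    for k, anchor in enumerate(DEFAULT_ANCHORS):
        delta = oriented_delta(merged[f"{anchor.name}_base"],
                               merged[f"{anchor.name}_fu"],
                               anchor.higher_is_better)
        for j, direction in enumerate(DIRECTIONS):
            mask = (merged["label"] == direction).to_numpy()
            est = wmw_power(PowerSpec(
                resampler(delta[mask]), resampler(delta[~mask]),
                n_a=int(mask.sum()), n_b=int((~mask).sum()),
                n_reps=args.n_reps, seed=args.seed + 7 * k + j))
            out[f"{direction}_{anchor.name}"] = {
                "power": est.power, "mc_se": est.mc_se,
                "n_a": est.n_a, "n_b": est.n_b,
            }
            print(f"{direction:9s} on {anchor.name:12s}: power "
                  f"{est.power:.3f} (mc se {est.mc_se:.3f}, "
                  f"n={est.n_a}/{est.n_b})")
    (args.out / "power.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
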