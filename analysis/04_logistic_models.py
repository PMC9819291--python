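"""The four logistic predictor models.

Fits worsened-vs-rest and improved-vs-rest logistic regressions on (a)
the baseline predictor pool and (b) the one-year-change pool, after
removing collinear predictors (HAQ-DI is dropped whenever it tracks
CHFS), and prints the odds-ratio table with Wald 95% intervals.

Outputs: results/logistic_models.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from facit_mcid.logistic_model import run_predictor_analyses, to_table_frame
from facit_mcid.synthetic_cohort import read_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.cohort)
    labels = pd.read_csv(args.labels)
    results = run_predictor_analyses(cohort, labels)
    table = to_table_frame(results)
    table.to_csv(args.out / "logistic_models.csv", index=False)

    for (direction, predictor_set), fit in results.items():
        if isinstance(fit, Exception):
            print(f"{direction}/{predictor_set}: {fit}")
            continue
        print(f"\n{direction}-vs-rest, {predictor_set} predictors "
              f"(n={fit.n}, events={fit.n_events}):")
        for name, row in fit.table.iterrows():
            if name == "const":
                continue
            star = "*" if row["p_value"] < 0.05 else " "
            print(f"  {star} {name:16s} OR {row['odds_ratio']:6.3f} "
                  f"CI {row['ci_low']:.3f}-{row['ci_high']:.3f} "
                  f"p {row['p_value']:.3f}")


if __name__ == "__main__":
    main()
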