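"""Exclude previously diagnosed participants, impute, and split the cohort.

Reads scratch/cohort.csv if 01_simulate_cohort.py produced it (otherwise
regenerates the default cohort), applies the study's preparation steps
and writes a split summary to results/split_summary.csv plus the
train/test CSVs to scratch/.
"""

import argparse
from pathlib import Path

import pandas as pd

from riskupdate.cohort import CohortConfig, generate_cohort, inject_missingness
from riskupdate.preprocessing import exclude_diagnosed, simple_impute, split_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0, help="cohort seed (if regenerating)")
    parser.add_argument("--split-seed", type=int, default=1)
    parser.add_argument("--fraction", type=float, default=2 / 3)
    args = parser.parse_args()

    src = ROOT / "scratch" / "cohort.csv"
    if src.exists():
        cohort = pd.read_csv(src)
        print(f"loaded {src}")
    else:
        cfg = CohortConfig(seed=args.seed)
        cohort = inject_missingness(generate_cohort(cfg), cfg.missingness_rates,
                                    seed=args.seed + 1)
        print("regenerated default cohort")

    analyzable = exclude_diagnosed(cohort)
    n_missing_rows = int(analyzable.drop(columns=["outcome"]).isna().any(axis=1).sum())
    imputed = simple_impute(analyzable)
    split = split_cohort(imputed, fraction=args.fraction, seed=args.split_seed)

    print(f"recruited {len(cohort)} -> analyzable {len(analyzable)} "
          f"(excluded {len(cohort) - len(analyzable)} previously diagnosed)")
    print(f"rows with any missing predictor before imputation: {n_missing_rows} "
          f"({100 * n_missing_rows / len(analyzable):.1f}%)")
    print(f"split: train {len(split.train)}, test {len(split.test)}")
    rows = [
        {"dataset": "train", "n": len(split.train),
         "events": int(split.train['outcome'].sum()),
         "prevalence": split.train["outcome"].mean()},
        {"dataset": "test", "n": len(split.test),
         "events": int(split.test['outcome'].sum()),
         "prevalence": split.test["outcome"].mean()},
    ]
    summary = pd.DataFrame(rows)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "split_summary.csv", index=False)
    split.train.to_csv(ROOT / "scratch" / "train.csv", index=False)
    split.test.to_csv(ROOT / "scratch" / "test.csv", index=False)
    print("wrote results/split_summary.csv, scratch/train.csv, scratch/test.csv")


if __name__ == "__main__":
    main()
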