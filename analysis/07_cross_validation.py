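#!/usr/bin/env python
"""Cross-validated diagnostic performance.

Runs the full learn-and-diagnose pipeline in stratified 10-fold
cross-validation over examination rows and reports the 3-class confusion
matrix, overall accuracy, and dementia-vs-HC sensitivity/specificity.
"""

import argparse
import json
from pathlib import Path

from cogbn.evaluate import CVConfig, cross_validate
from cogbn.io import read_cohort_csv
from cogbn.variables import STATUS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--folds", type=int, default=10)
    ap.add_argument("--scope", choices=["fold", "global"], default="fold")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort_csv(args.cohort)
    config = CVConfig(folds=args.folds, discretization_scope=args.scope,
                      bootstrap_B=25, repeats=10, n_samples=500)
    report = cross_validate(table, config, seed=args.seed)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "cv_report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    report.confusion.to_csv(args.out_dir / "confusion.csv")

    majority = table[STATUS].value_counts(normalize=True).max()
    print("confusion matrix (rows true, columns predicted):")
    print(report.confusion.to_string())
    print(f"\naccuracy    {report.accuracy:.4f} "
          f"(majority-class baseline {majority:.4f})")
    print(f"sensitivity {report.sensitivity:.4f}  (dementia vs HC)")
    print(f"specificity {report.specificity:.4f}")


if __name__ == "__main__":
    main()
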