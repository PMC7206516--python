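#!/usr/bin/env python
"""Stratified sub-analyses by sex, ApoE4 carrier status and education.

Repeats the learn + blanket pipeline within each stratum and compares the
first precursors (deepest status ancestors) and blankets across strata.
Cross-validation inside strata is skipped here to keep the driver quick;
pass --with-cv to include it.
"""

import argparse
import json
from pathlib import Path

from cogbn.evaluate import CVConfig, stratified_networks
from cogbn.io import read_cohort_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--with-cv", action="store_true")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort_csv(args.cohort)
    config = CVConfig(bootstrap_B=50)
    summary = {}
    for strata in ("sex", "apoe4", "education"):
        results = stratified_networks(table, strata, config, seed=args.seed,
                                      run_cv=args.with_cv)
        print(f"\n=== stratified by {strata} ===")
        for res in results:
            if res.skipped_reason:
                print(f"  {res.stratum}: skipped ({res.skipped_reason})")
                continue
            print(f"  {res.stratum}: n={res.n_rows}, "
                  f"excluded {res.excluded['missing_stratifier']} rows "
                  f"missing the stratifier")
            print(f"    first precursors: {', '.join(res.precursors) or '-'}")
            print(f"    blanket: {', '.join(res.blanket.blanket)}")
            if res.cv is not None:
                print(f"    CV accuracy: {res.cv.accuracy:.3f}")
            summary[res.stratum] = {
                "n_rows": res.n_rows,
                "edges": res.dag.edges(),
                "precursors": res.precursors,
                "blanket": list(res.blanket.blanket),
                "cv_accuracy": None if res.cv is None else res.cv.accuracy,
            }
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "stratified.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
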