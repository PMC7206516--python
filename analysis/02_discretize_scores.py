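#!/usr/bin/env python
"""Discretize the cohort's continuous scores.

Fits per-test interval maps by 1-D k-medoids with silhouette-selected k
and prints them in the "(lo,hi), (lo,hi), ..." layout used for published
discretization tables.
"""

import argparse
from pathlib import Path

from cogbn.discretize import fit_discretization
from cogbn.io import read_cohort_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--k-max", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort_csv(args.cohort)
    dmap = fit_discretization(table, k_max=args.k_max)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "discretization.json").write_text(dmap.to_json())
    (args.out_dir / "discretization.txt").write_text(dmap.to_text())

    print("chosen k and mean silhouette per test:")
    for var in dmap.intervals:
        print(f"  {var:8s} k={dmap.chosen_k[var]:2d}  "
              f"s={dmap.silhouette[var]:.3f}")
    print("\nscore intervals:")
    print(dmap.to_text())


if __name__ == "__main__":
    main()
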