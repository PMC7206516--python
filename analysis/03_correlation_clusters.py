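#!/usr/bin/env python
"""Cognitive-function cluster analysis.

Computes pairwise Pearson correlations between the 11 tests, extracts
clusters at the 0.6 cutoff, and tests each score's association with
cognitive status (one-way ANOVA, Bonferroni, Tukey-Kramer).
"""

import argparse
import json
from pathlib import Path

from cogbn.correlation import (
    correlation_matrix,
    extract_clusters,
    plot_correlation_heatmap,
    status_association,
)
from cogbn.io import read_cohort_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--cutoff", type=float, default=0.6)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort_csv(args.cohort)
    report = correlation_matrix(table)
    clusters = extract_clusters(report.matrix, cutoff=args.cutoff)
    anova = status_association(table)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    report.matrix.to_csv(args.out_dir / "correlation.csv")
    (args.out_dir / "clusters.json").write_text(json.dumps(
        {"cutoff": args.cutoff, "clusters": clusters}, indent=2))
    anova.to_csv(args.out_dir / "status_association.csv")
    plot_correlation_heatmap(report, args.out_dir / "correlation.png",
                             clusters=clusters)

    print(f"clusters at r >= {args.cutoff}:")
    for c in clusters:
        print("  " + ", ".join(c))
    print("\ncorrelation matrix:")
    print(report.matrix.round(2).to_string())
    print("\nassociation with status (Bonferroni-adjusted p):")
    print(anova[["F", "p_bonferroni"]].round(4).to_string())


if __name__ == "__main__":
    main()
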