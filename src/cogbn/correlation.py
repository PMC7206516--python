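"""Cognitive-function cluster analysis over the 11-test battery.

Pairwise Pearson correlations of the raw scores (pairwise-complete
observations), cluster extraction as connected components of the graph
thresholded at r >= 0.6, and per-test association with cognitive status by
one-way ANOVA with Bonferroni correction plus Tukey-Kramer pairwise
comparisons.  A chi-square independence test on the discretized pair is
available alongside the correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, DiscreteDataset
from .variables import NP_TESTS, STATUS, STATUS_STATES

__all__ = [
    "CorrelationReport",
    "correlation_matrix",
    "extract_clusters",
    "status_association",
    "chi2_pair",
]

DEFAULT_CUTOFF = 0.6


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    pair_n: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF
    clusters: list = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(m)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


def correlation_matrix(table: pd.DataFrame, variables=None,
                       min_pair_n: int = 3) -> CorrelationReport:
    """Pearson correlations on raw scores, pairwise-complete observations.

    Raises when any pair has fewer than ``min_pair_n`` complete rows.
    """
    variables = list(variables) if variables is not None else [
        c for c in NP_TESTS if c in table.columns
    ]
    sub = table[variables].astype(float)
    present = sub.notna().to_numpy().astype(np.int64)
    pair_n = present.T @ present
    if (pair_n < min_pair_n).any():
        i, j = np.argwhere(pair_n < min_pair_n)[0]
        raise ValueError(
            f"pair ({variables[i]}, {variables[j]}) has only "
            f"{pair_n[i, j]} complete rows (need >= {min_pair_n})"
        )
    corr = sub.corr(method="pearson")
    return CorrelationReport(
        matrix=corr,
        pair_n=pd.DataFrame(pair_n, index=variables, columns=variables),
    )


def extract_clusters(matrix: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                     use_abs: bool = False) -> list[list[str]]:
    """Connected components of the graph with an edge wherever r >= cutoff.

    Singleton clusters are allowed.  With ``use_abs`` the threshold is
    applied to |r| (all within-battery correlations are positive in the
    reference cohort, so the default thresholds the signed value).
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    if use_abs:
        vals = np.abs(vals)
    names = list(matrix.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if vals[i, j] >= cutoff:
                g.add_edge(names[i], names[j])
    return sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda c: (-len(c), c),
    )


def status_association(table: pd.DataFrame, variables=None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-test ANOVA across status groups plus Tukey-Kramer comparisons.

    Returns one row per test with the F statistic, raw p, Bonferroni
    adjusted p (factor = number of tests analysed) and the Tukey-Kramer
    p-value of each pairwise group contrast (studentized range under
    unequal group sizes).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    variables = list(variables) if variables is not None else [
        c for c in NP_TESTS if c in table.columns
    ]
    k = len(variables)
    rows = []
    for var in variables:
        sub = table[[var, STATUS]].dropna()
        groups = [
            sub.loc[sub[STATUS] == s, var].to_numpy(dtype=float)
            for s in STATUS_STATES
        ]
        n_groups = [len(g) for g in groups]
        if sum(n > 0 for n in n_groups) < 2 or any(
            0 < n < 2 for n in n_groups
        ):
            raise ValueError(
                f"{var}: need >=2 status groups with >=2 observations "
                f"(got sizes {n_groups})"
            )
        present = [g for g in groups if len(g)]
        f_stat, p = stats.f_oneway(*present)
        row = {
            "test": var,
            "F": float(f_stat),
            "p": float(p),
            "p_bonferroni": float(min(1.0, k * p)),
        }
        tk = pairwise_tukeyhsd(
            endog=sub[var].to_numpy(dtype=float),
            groups=sub[STATUS].to_numpy(),
            alpha=alpha,
        )
        frame = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        for _, r in frame.iterrows():
            row[f"tukey_{r['group1']}_vs_{r['group2']}"] = float(r["p-adj"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("test")


def plot_correlation_heatmap(report: CorrelationReport, path,
                             clusters=None) -> None:
    """Save a correlation heat map, with cluster boxes when provided."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.matrix.index)
    if clusters:
        order = [t for c in clusters for t in c]
        m = report.matrix.loc[order, order]
    else:
        order, m = names, report.matrix
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if clusters:
        start = 0
        for c in clusters:
            ax.add_patch(plt.Rectangle(
                (start - 0.5, start - 0.5), len(c), len(c),
                fill=False, edgecolor="red", linewidth=1.5))
            start += len(c)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def chi2_pair(data: DiscreteDataset, x: str, y: str) -> tuple[float, int, float]:
    """Pearson chi-square independence test of two discretized variables."""
    X = data.matrix([x, y])
    X = X[(X != MISSING).all(axis=1)]
    table = pd.crosstab(X[:, 0], X[:, 1]).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
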