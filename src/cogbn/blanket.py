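"""Markov-blanket extraction and conditional-independence testing.

The Markov blanket of the status node — its parents, children and spouses
(co-parents of its children) — is the smallest set of tests S such that
P(Status | all tests) = P(Status | S).  Conditional independence of a test
and status given a conditioning set is assessed by a stratified Pearson
chi-square with adjusted degrees of freedom: within each stratum of the
conditioning variables, rows and columns with zero margin are dropped
before computing the statistic and the stratum's df, and empty strata
contribute nothing.  Conditioning on a set that determines the target
collapses every stratum to zero df, which is what drives the p ~ 1
behaviour for tests outside the blanket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, DiscreteDataset
from .params import BNModel
from .structure import DAG
from .variables import NP_TESTS, STATUS

__all__ = ["BlanketReport", "markov_blanket", "chi2_ci_test",
           "blanket_sufficiency", "ci_table"]


@dataclass
class BlanketReport:
    target: str
    parents: tuple[str, ...]
    children: tuple[str, ...]
    spouses: tuple[str, ...]
    ci_tests: pd.DataFrame | None = None

    @property
    def blanket(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.parents) | set(self.children)
                            | set(self.spouses)))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "parents": list(self.parents),
            "children": list(self.children),
            "spouses": list(self.spouses),
            "blanket": list(self.blanket),
        }


def markov_blanket(dag: DAG, target: str = STATUS) -> BlanketReport:
    """Parents, children and spouses of ``target`` in ``dag``."""
    if target not in dag.nodes:
        raise KeyError(f"node {target!r} not in DAG")
    parents = set(dag.parents(target))
    children = set(dag.children(target))
    spouses = set()
    for c in children:
        spouses |= set(dag.parents(c))
    spouses -= {target}
    spouses -= parents | children  # report each node in one role only
    return BlanketReport(
        target=target,
        parents=tuple(sorted(parents)),
        children=tuple(sorted(children)),
        spouses=tuple(sorted(spouses)),
    )


def chi2_ci_test(x: str, y: str, z_set, data: DiscreteDataset
                 ) -> tuple[float, int, float]:
    """Stratified Pearson chi-square test of X ⊥ Y given Z.

    Returns ``(statistic, adjusted_df, p)``.  The statistic sums the
    Pearson X² of the x-by-y table within each stratum of Z; the df sums
    ``(r_x* - 1)(r_y* - 1)`` over strata, where the starred counts exclude
    empty rows/columns within the stratum.  A non-positive total df yields
    p = 1.
    """
    if x == y:
        raise ValueError("x and y must be distinct variables")
    z_set = list(z_set)
    cols = [x, y, *z_set]
    X = data.matrix(cols)
    X = X[(X != MISSING).all(axis=1)]
    if len(X) == 0:
        raise ValueError("no complete cases on the test variables")
    if z_set:
        strata_codes = np.zeros(len(X), dtype=np.int64)
        for i, z in enumerate(z_set):
            strata_codes = strata_codes * data.cards[z] + X[:, 2 + i]
    else:
        strata_codes = np.zeros(len(X), dtype=np.int64)
    stat_total, df_total = 0.0, 0
    for code in np.unique(strata_codes):
        sub = X[strata_codes == code]
        table = pd.crosstab(sub[:, 0], sub[:, 1]).to_numpy(dtype=float)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        rx, ry = table.shape
        df = (rx - 1) * (ry - 1)
        if df <= 0:
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        stat_total += float(((table - expected) ** 2 / expected).sum())
        df_total += df
    if df_total <= 0:
        return stat_total, 0, 1.0
    return stat_total, df_total, float(stats.chi2.sf(stat_total, df_total))


#: Default conditioning menu: the empty set, each of the two most frequent
#: blanket parents in the reference networks, and both together.
DEFAULT_CONDITION_SETS = ((), ("VRd",), ("LMi",), ("VRd", "LMi"))


def ci_table(data: DiscreteDataset, target: str = STATUS,
             condition_sets=DEFAULT_CONDITION_SETS,
             tests=None) -> pd.DataFrame:
    """Status-association p-values per test under each conditioning set."""
    tests = list(tests) if tests is not None else [
        t for t in NP_TESTS if t in data.columns
    ]
    rows = []
    for t in tests:
        row: dict = {"test": t}
        for z in condition_sets:
            z_use = tuple(v for v in z if v != t)
            label = "phi" if not z else "+".join(z)
            stat, df, p = chi2_ci_test(t, target, z_use, data)
            row[f"p[{label}]"] = p
            row[f"df[{label}]"] = df
        rows.append(row)
    return pd.DataFrame(rows).set_index("test")


def blanket_sufficiency(model: BNModel, data: DiscreteDataset,
                        n_rows: int = 200, target: str = STATUS,
                        subset=None, seed: int = 0) -> float:
    """Max total-variation gap between P(target | all tests) and
    P(target | blanket tests) over evidence rows.

    Both posteriors are exact.  ``subset`` overrides the blanket (used to
    show that non-blanket subsets lose information).  Evidence rows are
    drawn from ``data``'s complete cases.
    """
    from .inference import exact_posterior

    blanket = tuple(subset) if subset is not None else (
        markov_blanket(model.dag, target).blanket
    )
    tests = [v for v in model.nodes if v != target]
    complete = data.complete_cases(list(model.nodes))
    if complete.n_rows == 0:
        raise ValueError("no complete evidence rows")
    rng = np.random.default_rng(seed)
    idx = rng.choice(complete.n_rows, size=min(n_rows, complete.n_rows),
                     replace=False)
    worst = 0.0
    seen = set()
    for i in idx:
        row = {v: int(complete.codes.at[i, v]) for v in tests}
        key = tuple(sorted(row.items()))
        if key in seen:
            continue
        seen.add(key)
        full = exact_posterior(model, row, target)
        sub = exact_posterior(
            model, {v: s for v, s in row.items() if v in blanket}, target
        )
        worst = max(worst, full.tv_distance(sub))
    return worst
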