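"""Conditional probability table (CPT) estimation for a fixed network.

Two estimators are provided: maximum likelihood (relative frequencies per
parent configuration) and the Bayesian posterior mean under a uniform
Dirichlet prior with total imaginary sample size ``iss`` spread evenly over
the ``q * r`` cells of each table.  The Bayesian fit is strictly positive,
which likelihood-weighting inference needs (zero rows would zero out sample
weights), and is therefore the default feeding inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DiscreteDataset
from .structure import DAG
from .variables import VariableSpec

__all__ = ["CPT", "BNModel", "fit_mle", "fit_bayes"]

_ROW_TOL = 1e-9


@dataclass
class CPT:
    """Distribution of ``node`` over its states for each parent configuration.

    ``table`` has shape ``(q, r)`` with ``q`` the product of parent
    cardinalities (row index is the mixed-radix rank of the parent states,
    first parent most significant) and ``r`` the node cardinality.
    """

    node: str
    parents: tuple[str, ...]
    parent_cards: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if self.table.ndim != 2 or self.table.shape[0] != q:
            raise ValueError(
                f"{self.node}: table shape {self.table.shape} does not cover "
                f"the {q} parent configurations"
            )
        if (self.table < -_ROW_TOL).any():
            raise ValueError(f"{self.node}: negative probabilities")
        sums = self.table.sum(axis=1)
        if np.abs(sums - 1.0).max() > _ROW_TOL:
            raise ValueError(f"{self.node}: CPT rows must sum to 1")

    @property
    def cardinality(self) -> int:
        return self.table.shape[1]

    def row_index(self, parent_states) -> int:
        idx = 0
        for card, s in zip(self.parent_cards, parent_states):
            idx = idx * card + int(s)
        return idx

    def row(self, parent_states) -> np.ndarray:
        return self.table[self.row_index(parent_states)]


@dataclass
class BNModel:
    """A discrete Bayesian network: DAG plus one CPT per node."""

    dag: DAG
    cpts: dict[str, CPT]
    variables: list[VariableSpec] = field(default_factory=list)
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            if v not in self.cpts:
                raise ValueError(f"missing CPT for node {v!r}")
            if self.cpts[v].parents != self.dag.parents(v):
                raise ValueError(
                    f"CPT parents {self.cpts[v].parents} of {v!r} do not "
                    f"match DAG parents {self.dag.parents(v)}"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    @property
    def cards(self) -> dict[str, int]:
        return {v: self.cpts[v].cardinality for v in self.nodes}

    def topological_order(self) -> list[str]:
        order: list[str] = []
        placed: set = set()
        pending = list(self.nodes)
        while pending:
            progressed = False
            for v in list(pending):
                if set(self.dag.parents(v)) <= placed:
                    order.append(v)
                    placed.add(v)
                    pending.remove(v)
                    progressed = True
            if not progressed:  # pragma: no cover - DAG class forbids cycles
                raise ValueError("graph has no topological order")
        return order

    def spec(self, name: str) -> VariableSpec:
        for s in self.variables:
            if s.name == name:
                return s
        raise KeyError(name)


def _family_counts(data: DiscreteDataset, node: str, parents: tuple[str, ...],
                   cards: dict[str, int]) -> np.ndarray:
    cols = [node, *parents]
    X = data.matrix(cols)
    X = X[(X >= 0).all(axis=1)]
    r = cards[node]
    q = int(np.prod([cards[p] for p in parents])) if parents else 1
    config = np.zeros(len(X), dtype=np.int64)
    for i, p in enumerate(parents):
        config = config * cards[p] + X[:, i + 1]
    counts = np.bincount(config * r + X[:, 0], minlength=q * r)
    return counts.reshape(q, r).astype(float)


def _fit(dag: DAG, data: DiscreteDataset, iss: float | None,
         variables) -> BNModel:
    complete = data.complete_cases(list(dag.nodes))
    if complete.n_rows == 0:
        raise ValueError("no complete-case rows to estimate from")
    cards = {v: data.cards[v] for v in dag.nodes}
    cpts: dict[str, CPT] = {}
    uniform_rows: dict[str, int] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        counts = _family_counts(complete, v, parents, cards)
        q, r = counts.shape
        if iss is None:  # maximum likelihood
            n_j = counts.sum(axis=1, keepdims=True)
            empty = n_j[:, 0] == 0
            table = np.where(n_j > 0, counts / np.where(n_j > 0, n_j, 1.0),
                             1.0 / r)
            uniform_rows[v] = int(empty.sum())
        else:
            a_cell = iss / (q * r)
            table = (counts + a_cell) / (counts.sum(axis=1, keepdims=True)
                                         + iss / q)
        cpts[v] = CPT(node=v, parents=parents,
                      parent_cards=tuple(cards[p] for p in parents),
                      table=table)
    report = {
        "estimator": "mle" if iss is None else "bayes",
        "iss": iss,
        "n_rows_used": complete.n_rows,
        "uniform_rows": uniform_rows if iss is None else {},
    }
    return BNModel(dag=dag.copy(), cpts=cpts,
                   variables=list(variables or []), fit_report=report)


def fit_mle(dag: DAG, data: DiscreteDataset, variables=None) -> BNModel:
    """Maximum-likelihood CPTs: row ``j`` is ``n_jk / n_j``.

    Parent configurations never observed get a uniform row; their count is
    recorded in ``fit_report["uniform_rows"]``.
    """
    return _fit(dag, data, iss=None, variables=variables)


def fit_bayes(dag: DAG, data: DiscreteDataset, iss: float = 1.0,
              variables=None) -> BNModel:
    """Dirichlet posterior-mean CPTs with imaginary sample size ``iss``.

    Row entry ``(n_jk + iss/(r q)) / (n_j + iss/q)``; strictly positive for
    any ``iss > 0``, and converging to the MLE as ``iss`` vanishes on rows
    with observed support.
    """
    if iss <= 0:
        raise ValueError("iss must be positive")
    return _fit(dag, data, iss=iss, variables=variables)
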