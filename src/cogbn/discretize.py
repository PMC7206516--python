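"""Score discretization by 1-D k-medoids (PAM) with silhouette-chosen k.

Each continuous test score is clustered on the real line with partitioning
around medoids under absolute-difference distance: greedy BUILD
initialisation followed by best-improvement SWAP steps.  The number of
clusters is chosen (per variable, over k = 2..k_max) to maximise the mean
silhouette width.  Clusters become ordered closed score intervals spanning
the observed extremes of each cluster, the same shape as published
interval maps for these tests.

Determinism: assignment ties go to the lower medoid; BUILD/SWAP cost ties
prefer the lexicographically smaller medoid set; silhouette ties across k
prefer the smaller k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, DiscreteDataset
from .variables import NP_TESTS, STATUS, STATUS_STATES, VariableSpec

__all__ = [
    "DiscretizationMap",
    "InfeasibleKError",
    "DegenerateVariableError",
    "pam_1d",
    "silhouette_width",
    "fit_discretization",
    "apply_discretization",
]


class InfeasibleKError(ValueError):
    """k exceeds the number of distinct values."""


class DegenerateVariableError(ValueError):
    """A column is constant (or empty) and cannot be discretized."""


# ---------------------------------------------------------------------------
# PAM on the line
# ---------------------------------------------------------------------------

def _unique_weighted(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals = np.asarray(values, dtype=float)
    if np.isnan(vals).any():
        raise ValueError("values must be non-missing")
    return np.unique(vals, return_counts=True)


def _total_cost(dist: np.ndarray, weights: np.ndarray,
                medoid_idx: tuple) -> float:
    # dist: (u, u) abs-difference matrix over unique values
    return float((dist[:, list(medoid_idx)].min(axis=1) * weights).sum())


def pam_1d(values, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids for 1-D data.

    Returns ``(medoids, assignment)``: the final medoids sorted ascending
    and each input value's 0-based cluster label (clusters ordered by
    medoid).  Raises :class:`InfeasibleKError` when ``k`` exceeds the
    number of distinct values.
    """
    vals = np.asarray(values, dtype=float)
    uniq, counts = _unique_weighted(vals)
    u = len(uniq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > u:
        raise InfeasibleKError(f"k={k} exceeds {u} distinct values")
    dist = np.abs(uniq[:, None] - uniq[None, :])
    w = counts.astype(float)

    # BUILD: greedily add the medoid that most reduces total cost; ties by
    # smaller value (indices are sorted, so first argmin wins).
    chosen: list[int] = []
    nearest = np.full(u, np.inf)
    for _ in range(k):
        reduction = (np.minimum(dist, nearest[:, None]) * w[:, None]).sum(axis=0)
        reduction[chosen] = np.inf
        best = int(np.argmin(reduction))
        chosen.append(best)
        nearest = np.minimum(nearest, dist[:, best])

    # SWAP: accept the single best strictly-improving medoid/non-medoid
    # exchange until none exists; cost ties prefer the lexicographically
    # smaller medoid set.
    current = tuple(sorted(chosen))
    cost = _total_cost(dist, w, current)
    improved = True
    while improved:
        improved = False
        best_set, best_cost = current, cost
        for out in current:
            for inn in range(u):
                if inn in current:
                    continue
                cand = tuple(sorted(set(current) - {out} | {inn}))
                c = _total_cost(dist, w, cand)
                if c < best_cost - 1e-12 or (
                    abs(c - best_cost) <= 1e-12 and cand < best_set
                ):
                    best_set, best_cost = cand, c
        if best_set != current:
            current, cost = best_set, best_cost
            improved = True

    medoids = uniq[list(current)]
    # nearest-medoid assignment, ties to the lower medoid
    d_to_m = np.abs(vals[:, None] - medoids[None, :])
    assignment = np.argmin(d_to_m, axis=1)  # argmin takes the first (lower)
    return medoids, assignment


def silhouette_width(values, assignment) -> float:
    """Mean silhouette width of a 1-D clustering under |x - y| distance.

    Per point, ``s = (b - a) / max(a, b)`` with ``a`` the mean distance to
    the point's own cluster (excluding itself) and ``b`` the smallest mean
    distance to any other cluster; singleton-cluster points score 0.
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(assignment)
    uniq_labels = np.unique(labels)
    if len(uniq_labels) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    sums = {}
    sizes = {}
    for lab in uniq_labels:
        members = vals[labels == lab]
        if len(members) == 0:
            raise ValueError(f"cluster {lab} is empty")
        sizes[lab] = len(members)
        sums[lab] = members
    s_total = 0.0
    for x, lab in zip(vals, labels):
        if sizes[lab] == 1:
            continue  # s = 0
        a = np.abs(sums[lab] - x).sum() / (sizes[lab] - 1)
        b = min(
            np.abs(sums[o] - x).mean() for o in uniq_labels if o != lab
        )
        denom = max(a, b)
        s_total += 0.0 if denom == 0 else (b - a) / denom
    return s_total / len(vals)


# ---------------------------------------------------------------------------
# Interval maps
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationMap:
    """Per-variable ordered closed score intervals with fit diagnostics."""

    intervals: dict[str, tuple[tuple[float, float], ...]]
    chosen_k: dict[str, int] = field(default_factory=dict)
    silhouette: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, ivs in self.intervals.items():
            for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
                if not hi1 < lo2:
                    raise ValueError(
                        f"{var}: intervals {ivs} not sorted/disjoint")
            for lo, hi in ivs:
                if lo > hi:
                    raise ValueError(f"{var}: inverted interval ({lo},{hi})")

    @classmethod
    def from_variable_specs(cls, specs) -> "DiscretizationMap":
        ivs = {s.name: tuple(s.levels) for s in specs if s.kind == "np_test"}
        return cls(intervals=ivs,
                   chosen_k={v: len(i) for v, i in ivs.items()})

    def bin_index(self, var: str, value: float) -> int:
        for j, (lo, hi) in enumerate(self.intervals[var]):
            if lo - 1e-9 <= value <= hi + 1e-9:
                return j
        raise ValueError(
            f"{var}: value {value} outside interval table "
            f"{self.intervals[var]}"
        )

    def cards(self) -> dict[str, int]:
        return {v: len(ivs) for v, ivs in self.intervals.items()}

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "intervals": {v: [list(iv) for iv in ivs]
                          for v, ivs in self.intervals.items()},
            "chosen_k": self.chosen_k,
            "silhouette": self.silhouette,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        raw = json.loads(text)
        return cls(
            intervals={v: tuple(tuple(iv) for iv in ivs)
                       for v, ivs in raw["intervals"].items()},
            chosen_k={v: int(k) for v, k in raw.get("chosen_k", {}).items()},
            silhouette={v: float(s)
                        for v, s in raw.get("silhouette", {}).items()},
        )

    def to_text(self) -> str:
        """Human-readable "(lo,hi), (lo,hi), ..." interval listing."""
        def fmt(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x}"

        lines = []
        for var, ivs in self.intervals.items():
            body = ", ".join(f"({fmt(lo)},{fmt(hi)})" for lo, hi in ivs)
            lines.append(f"{var}\t{body}")
        return "\n".join(lines) + "\n"


def fit_discretization(table: pd.DataFrame, k_max: int = 10,
                       variables=None) -> DiscretizationMap:
    """Fit per-variable interval maps by PAM + silhouette model selection.

    For each variable, k = 2..min(k_max, #distinct values) are scored by
    mean silhouette width (ties to the smaller k); the winning clustering
    is turned into closed intervals spanning each cluster's observed
    extremes.
    """
    variables = list(variables) if variables is not None else [
        c for c in table.columns if c in NP_TESTS
    ]
    intervals: dict = {}
    chosen_k: dict = {}
    sil: dict = {}
    for var in variables:
        vals = table[var].dropna().to_numpy(dtype=float)
        distinct = np.unique(vals)
        if len(distinct) < 2:
            raise DegenerateVariableError(
                f"column {var!r} has fewer than 2 distinct values")
        best_k, best_s, best_assign = None, -np.inf, None
        for k in range(2, min(k_max, len(distinct)) + 1):
            _, assign = pam_1d(vals, k)
            s = silhouette_width(vals, assign)
            if s > best_s + 1e-12:
                best_k, best_s, best_assign = k, s, assign
        ivs = []
        for lab in range(best_k):
            members = vals[best_assign == lab]
            ivs.append((float(members.min()), float(members.max())))
        intervals[var] = tuple(sorted(ivs))
        chosen_k[var] = best_k
        sil[var] = float(best_s)
    return DiscretizationMap(intervals=intervals, chosen_k=chosen_k,
                             silhouette=sil)


def apply_discretization(table: pd.DataFrame, dmap: DiscretizationMap
                         ) -> DiscreteDataset:
    """Replace scores by 0-based interval indices; missing stays missing.

    Status and covariate columns pass through (status is coded HC=0, AD=1,
    NAD=2).  A score outside its variable's interval table raises a range
    error naming the variable, the value and the table.
    """
    codes = {}
    cards = dict(dmap.cards())
    for var, ivs in dmap.intervals.items():
        if var not in table.columns:
            raise KeyError(f"variable {var!r} missing from table")
        vals = table[var].to_numpy(dtype=float)
        out = np.full(len(vals), MISSING, dtype=np.int64)
        present = ~np.isnan(vals)
        los = np.array([lo for lo, _ in ivs])
        his = np.array([hi for _, hi in ivs])
        v = vals[present]
        inside = (v[:, None] >= los[None, :] - 1e-9) & (
            v[:, None] <= his[None, :] + 1e-9)
        hit = inside.sum(axis=1)
        if (hit == 0).any():
            bad = v[hit == 0][0]
            raise ValueError(
                f"{var}: score {bad} outside interval table {ivs}")
        out[present] = np.argmax(inside, axis=1)
        codes[var] = out
    if STATUS in table.columns:
        status = table[STATUS].map(
            {s: i for i, s in enumerate(STATUS_STATES)})
        if status.isna().any():
            raise ValueError("status column contains missing/unknown labels")
        codes[STATUS] = status.to_numpy(dtype=np.int64)
        cards[STATUS] = len(STATUS_STATES)
    passthrough_cols = [c for c in table.columns
                        if c not in codes]
    passthrough = table[passthrough_cols].copy() if passthrough_cols else None
    return DiscreteDataset(codes=pd.DataFrame(codes), cards=cards,
                           passthrough=passthrough)
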