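"""Score-based structure learning for discrete Bayesian networks.

The score is the BIC / MDL network score: multinomial log-likelihood of the
data minus ``(log N / 2) * q * (r - 1)`` per family, where ``r`` is the
child's cardinality and ``q`` the number of parent configurations with
observed support.  The score decomposes over families, so local search can
re-score only the families a move touches.

Search is greedy hill-climbing over single-edge moves (add / delete /
reverse) with optional random restarts, plus a tabu variant that escapes
local optima by accepting the least-worsening non-tabu move.  Model
averaging over nonparametric bootstrap resamples yields per-edge strength
and direction frequencies and an averaged network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .dataset import DiscreteDataset

__all__ = [
    "DAG",
    "EdgeSupport",
    "CycleError",
    "family_bic",
    "bic_score",
    "hill_climb",
    "tabu_search",
    "bootstrap_average",
    "enumerate_dags",
    "exhaustive_search",
    "structural_hamming_distance",
]


class CycleError(ValueError):
    """Raised when an operation would create (or was given) a directed cycle."""


class DAG:
    """Directed acyclic graph over named nodes.

    Mutating operations (:meth:`add_edge`, :meth:`reverse_edge`) maintain
    acyclicity and raise :class:`CycleError` on violation.
    """

    __slots__ = ("nodes", "_parents")

    def __init__(self, nodes, edges=()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set] = {v: set() for v in self.nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- queries ----------------------------------------------------------
    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[v]))

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(u for u in self.nodes if v in self._parents[u]))

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def edges(self) -> list[tuple[str, str]]:
        return sorted((u, v) for v in self.nodes for u in self._parents[v])

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self._parents.values())

    def ancestors(self, v: str) -> set:
        """All nodes with a directed path to ``v``."""
        seen: set = set()
        stack = list(self._parents[v])
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(self._parents[u])
        return seen

    def would_cycle(self, u: str, v: str) -> bool:
        """True if adding u -> v would close a directed cycle."""
        return u == v or u in self._reachable_from(v)

    def _reachable_from(self, v: str) -> set:
        """Descendant closure of v (nodes reachable by directed paths)."""
        seen: set = set()
        stack = [c for c in self.nodes if v in self._parents[c]]
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(c for c in self.nodes if u in self._parents[c])
        return seen

    # -- mutation ---------------------------------------------------------
    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u}->{v}")
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in edge {u}->{v}")
        if u in self._parents[v]:
            raise ValueError(f"duplicate edge {u}->{v}")
        if u in self._reachable_from(v):
            raise CycleError(f"edge {u}->{v} would create a cycle")
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        self._parents[v].remove(u)

    def reverse_edge(self, u: str, v: str) -> None:
        self.remove_edge(u, v)
        try:
            self.add_edge(v, u)
        except CycleError:
            self._parents[v].add(u)
            raise

    def copy(self) -> "DAG":
        g = DAG(self.nodes)
        g._parents = {v: set(p) for v, p in self._parents.items()}
        return g

    # -- conversions ------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DAG":
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError("input graph is cyclic")
        return cls(sorted(g.nodes), g.edges())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and set(self.nodes) == set(other.nodes)
            and self._parents == {v: other._parents[v] for v in self._parents}
        )

    def __repr__(self) -> str:
        return f"DAG(nodes={len(self.nodes)}, edges={self.edges()})"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class FamilyScorer:
    """Cached decomposable family scores on complete-case rows.

    All families are scored against the same complete-case row set so that
    deltas of local moves are comparable.
    """

    def __init__(self, data: DiscreteDataset, columns=None, score: str = "bic",
                 ess: float = 1.0):
        cols = list(columns) if columns is not None else data.columns
        sub = data.complete_cases(cols)
        self.columns = cols
        self.index = {c: i for i, c in enumerate(cols)}
        self.X = sub.matrix(cols)
        self.cards = {c: data.cards[c] for c in cols}
        self.N = self.X.shape[0]
        if self.N == 0:
            raise ValueError("no complete-case rows to score")
        self._logN = float(np.log(self.N))
        self.score = score
        self.ess = ess
        self._cache: dict = {}

    def family(self, node: str, parents) -> float:
        key = (node, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = self._compute(node, key[1])
        self._cache[key] = val
        return val

    def _compute(self, node: str, parents: tuple) -> float:
        r = self.cards[node]
        child = self.X[:, self.index[node]]
        if parents:
            q_full = 1
            config = np.zeros(self.N, dtype=np.int64)
            for p in parents:
                config = config * self.cards[p] + self.X[:, self.index[p]]
                q_full *= self.cards[p]
        else:
            q_full = 1
            config = np.zeros(self.N, dtype=np.int64)
        counts = np.bincount(config * r + child, minlength=q_full * r)
        counts = counts.reshape(q_full, r)
        n_j = counts.sum(axis=1)
        obs = n_j > 0
        c = counts[obs]
        nj = n_j[obs]
        q_obs = int(obs.sum())
        if self.score == "bdeu":
            a_jk = self.ess / (q_full * r)
            a_j = self.ess / q_full
            return float(
                np.sum(gammaln(a_j) - gammaln(a_j + nj))
                + np.sum(gammaln(a_jk + c) - gammaln(a_jk))
            )
        loglik = float(xlogy(c, c).sum() - xlogy(nj, nj).sum())
        if self.score == "bic":
            return loglik - 0.5 * self._logN * q_obs * (r - 1)
        if self.score == "aic":
            return loglik - q_obs * (r - 1)
        raise ValueError(f"unknown score {self.score!r}")

    def total(self, dag: DAG) -> float:
        return sum(self.family(v, dag.parents(v)) for v in dag.nodes)


def family_bic(node: str, parent_set, data: DiscreteDataset,
               score: str = "bic", ess: float = 1.0) -> float:
    """BIC contribution of one family, on rows complete for that family.

    ``sum_jk n_jk log(n_jk / n_j) - (log N / 2) q (r - 1)`` with ``q`` the
    number of parent configurations that actually occur in the data.
    """
    parent_set = tuple(parent_set)
    if node in parent_set:
        raise ValueError(f"node {node!r} cannot be its own parent")
    scorer = FamilyScorer(data, columns=[node, *parent_set], score=score, ess=ess)
    return scorer.family(node, parent_set)


def bic_score(dag: DAG | nx.DiGraph, data: DiscreteDataset,
              score: str = "bic", ess: float = 1.0) -> float:
    """Total decomposable network score on jointly complete rows."""
    if isinstance(dag, nx.DiGraph):
        dag = DAG.from_networkx(dag)
    unknown = set(dag.nodes) - set(data.columns)
    if unknown:
        raise ValueError(f"dag nodes missing from data: {sorted(unknown)}")
    scorer = FamilyScorer(data, columns=list(dag.nodes), score=score, ess=ess)
    return scorer.total(dag)


# ---------------------------------------------------------------------------
# Local search
# ---------------------------------------------------------------------------

_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def _candidate_moves(dag: DAG, blacklist: frozenset, whitelist: frozenset):
    """All legal single-edge moves in deterministic (u, v, type) order."""
    moves = []
    for u, v in itertools.permutations(dag.nodes, 2):
        if dag.has_edge(u, v):
            if (u, v) not in whitelist:
                moves.append(("delete", u, v))
            if (v, u) not in blacklist and (u, v) not in whitelist:
                moves.append(("reverse", u, v))
        elif (u, v) not in blacklist:
            moves.append(("add", u, v))
    moves.sort(key=lambda m: (m[1], m[2], _MOVE_ORDER[m[0]]))
    return moves


def _move_is_acyclic(dag: DAG, move) -> bool:
    kind, u, v = move
    if kind == "add":
        return u not in dag._reachable_from(v)
    if kind == "reverse":
        # v -> u legal iff no other directed path u ~> v
        dag.remove_edge(u, v)
        ok = v not in dag._reachable_from(u)
        dag._parents[v].add(u)
        return ok
    return True


def _move_delta(dag: DAG, move, scorer: FamilyScorer) -> float:
    kind, u, v = move
    pa_v = dag.parents(v)
    if kind == "add":
        return scorer.family(v, pa_v + (u,)) - scorer.family(v, pa_v)
    if kind == "delete":
        new_pa = tuple(x for x in pa_v if x != u)
        return scorer.family(v, new_pa) - scorer.family(v, pa_v)
    # reverse u->v into v->u
    pa_u = dag.parents(u)
    d = scorer.family(v, tuple(x for x in pa_v if x != u)) - scorer.family(v, pa_v)
    d += scorer.family(u, pa_u + (v,)) - scorer.family(u, pa_u)
    return d


def _apply_move(dag: DAG, move) -> None:
    kind, u, v = move
    if kind == "add":
        dag.add_edge(u, v)
    elif kind == "delete":
        dag.remove_edge(u, v)
    else:
        dag.reverse_edge(u, v)


_EPS = 1e-9


def _greedy_climb(dag: DAG, scorer: FamilyScorer, blacklist, whitelist,
                  max_iter: int) -> tuple[DAG, float]:
    score = scorer.total(dag)
    for _ in range(max_iter):
        best_delta, best_move = _EPS, None
        for move in _candidate_moves(dag, blacklist, whitelist):
            if not _move_is_acyclic(dag, move):
                continue
            delta = _move_delta(dag, move, scorer)
            if delta > best_delta + _EPS:
                best_delta, best_move = delta, move
        if best_move is None:
            break
        _apply_move(dag, best_move)
        score += best_delta
    return dag, score


def _normalise_constraints(blacklist, whitelist) -> tuple[frozenset, frozenset]:
    bl = frozenset(tuple(e) for e in (blacklist or ()))
    wl = frozenset(tuple(e) for e in (whitelist or ()))
    if bl & wl:
        raise ValueError("edge in both blacklist and whitelist")
    return bl, wl


def hill_climb(data: DiscreteDataset, init: DAG | None = None,
               max_iter: int = 10_000, restarts: int = 5, perturb: int = 3,
               seed: int = 0, score: str = "bic", ess: float = 1.0,
               blacklist=None, whitelist=None,
               scorer: FamilyScorer | None = None) -> DAG:
    """Greedy hill-climbing maximisation of the network score.

    Applies the best strictly-improving add/delete/reverse move until a
    local optimum; with ``restarts > 0``, re-climbs from randomly perturbed
    copies of the incumbent and keeps the best-scoring result.  Equal-delta
    moves are broken by (source, target, move-type) order, so the search is
    deterministic given ``seed``.
    """
    if scorer is None:
        scorer = FamilyScorer(data, score=score, ess=ess)
    bl, wl = _normalise_constraints(blacklist, whitelist)
    dag = init.copy() if init is not None else DAG(scorer.columns)
    for u, v in wl:
        if not dag.has_edge(u, v):
            dag.add_edge(u, v)
    rng = np.random.default_rng(seed)
    best, best_score = _greedy_climb(dag, scorer, bl, wl, max_iter)
    for _ in range(restarts):
        cand = best.copy()
        for _ in range(perturb):
            moves = [m for m in _candidate_moves(cand, bl, wl)
                     if _move_is_acyclic(cand, m)]
            if not moves:
                break
            _apply_move(cand, moves[rng.integers(len(moves))])
        cand, cand_score = _greedy_climb(cand, scorer, bl, wl, max_iter)
        if cand_score > best_score + _EPS:
            best, best_score = cand, cand_score
    return best


def tabu_search(data: DiscreteDataset, tabu_len: int = 10,
                max_iter: int = 10_000, seed: int = 0, patience: int = 50,
                init: DAG | None = None, score: str = "bic", ess: float = 1.0,
                blacklist=None, whitelist=None,
                scorer: FamilyScorer | None = None) -> DAG:
    """Tabu-list local search returning the best network ever visited.

    While improving moves exist the trajectory coincides with hill-climbing
    (same tie rules).  At a local optimum the least-worsening non-tabu move
    is accepted and its inverse enters a FIFO tabu list of length
    ``tabu_len``; a move that would beat the incumbent is always allowed
    (aspiration).  With ``tabu_len=0`` no worsening move is taken and the
    result equals plain hill-climbing without restarts.
    """
    if scorer is None:
        scorer = FamilyScorer(data, score=score, ess=ess)
    bl, wl = _normalise_constraints(blacklist, whitelist)
    dag = init.copy() if init is not None else DAG(scorer.columns)
    for u, v in wl:
        if not dag.has_edge(u, v):
            dag.add_edge(u, v)
    score_now = scorer.total(dag)
    best, best_score = dag.copy(), score_now
    tabu: list = []
    tabu_set: set = set()
    since_improve = 0
    for _ in range(max_iter):
        best_delta, best_move = None, None
        for move in _candidate_moves(dag, bl, wl):
            if not _move_is_acyclic(dag, move):
                continue
            delta = _move_delta(dag, move, scorer)
            if move in tabu_set and score_now + delta <= best_score + _EPS:
                continue  # tabu and no aspiration
            if best_delta is None or delta > best_delta + _EPS:
                best_delta, best_move = delta, move
        if best_move is None:
            break
        if tabu_len == 0 and best_delta <= _EPS:
            break
        _apply_move(dag, best_move)
        score_now += best_delta
        kind, u, v = best_move
        inverse = {"add": ("delete", u, v),
                   "delete": ("add", u, v),
                   "reverse": ("reverse", v, u)}[kind]
        if tabu_len > 0:
            tabu.append(inverse)
            tabu_set.add(inverse)
            if len(tabu) > tabu_len:
                old = tabu.pop(0)
                if old not in tabu:
                    tabu_set.discard(old)
        if score_now > best_score + _EPS:
            best, best_score = dag.copy(), score_now
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break
    return best


# ---------------------------------------------------------------------------
# Bootstrap model averaging
# ---------------------------------------------------------------------------

@dataclass
class EdgeSupport:
    """Bootstrap edge frequencies over ``B`` replicates.

    ``strength(u, v)`` is the fraction of replicate networks containing the
    edge in either direction; ``direction(u, v)`` the fraction of those that
    orient it u -> v.
    """

    nodes: tuple[str, ...]
    B: int
    _undirected: dict = field(default_factory=dict)   # frozenset({u,v}) -> count
    _directed: dict = field(default_factory=dict)     # (u, v) -> count

    def record(self, dag: DAG) -> None:
        for u, v in dag.edges():
            self._undirected[frozenset((u, v))] = (
                self._undirected.get(frozenset((u, v)), 0) + 1
            )
            self._directed[(u, v)] = self._directed.get((u, v), 0) + 1

    def strength(self, u: str, v: str) -> float:
        return self._undirected.get(frozenset((u, v)), 0) / self.B

    def direction(self, u: str, v: str) -> float:
        both = self._undirected.get(frozenset((u, v)), 0)
        if both == 0:
            return 0.0
        return self._directed.get((u, v), 0) / both

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, n_any in sorted(self._undirected.items(),
                                  key=lambda kv: tuple(sorted(kv[0]))):
            u, v = sorted(pair)
            rows.append({"from": u, "to": v,
                         "strength": n_any / self.B,
                         "direction": self.direction(u, v)})
            rows.append({"from": v, "to": u,
                         "strength": n_any / self.B,
                         "direction": self.direction(v, u)})
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


def bootstrap_average(data: DiscreteDataset, learner=None, B: int = 500,
                      strength_threshold: float = 0.5, seed: int = 0
                      ) -> tuple[EdgeSupport, DAG]:
    """Model averaging over nonparametric bootstrap resamples.

    Learns one network per row-resample, tabulates per-edge strength and
    direction frequencies, and assembles the averaged network from edges
    with strength at or above ``strength_threshold``, oriented by majority
    direction.  Any residual directed cycle is broken by dropping its
    lowest-strength edge.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if learner is None:
        def learner(d, s):
            return hill_climb(d, restarts=0, seed=s)
    rng = np.random.default_rng(seed)
    n = data.n_rows
    nodes: tuple[str, ...] | None = None
    support: EdgeSupport | None = None
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dag = learner(data.subset(idx), sub_seed)
        if support is None:
            nodes = dag.nodes
            support = EdgeSupport(nodes=nodes, B=B)
        support.record(dag)
    averaged = _assemble_average(support, strength_threshold)
    return support, averaged


def _assemble_average(support: EdgeSupport, threshold: float) -> DAG:
    picked = []
    for pair, n_any in support._undirected.items():
        if n_any / support.B < threshold:
            continue
        u, v = sorted(pair)
        if support.direction(u, v) >= 0.5:
            picked.append((u, v))
        else:
            picked.append((v, u))
    g = nx.DiGraph()
    g.add_nodes_from(support.nodes)
    g.add_edges_from(sorted(picked))
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda e: (support.strength(*e), e))
        g.remove_edge(*weakest[:2])
    return DAG(support.nodes, g.edges())


# ---------------------------------------------------------------------------
# Enumeration utilities (oracles for small problems)
# ---------------------------------------------------------------------------

def enumerate_dags(nodes):
    """Yield every labelled DAG over ``nodes`` (feasible up to ~4 nodes)."""
    nodes = tuple(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    # each unordered pair is absent, forward, or backward
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (u, v), s in zip(pairs, states):
            if s == 1:
                g.add_edge(u, v)
            elif s == 2:
                g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g):
            yield DAG(nodes, g.edges())


def exhaustive_search(data: DiscreteDataset, score: str = "bic",
                      ess: float = 1.0) -> tuple[DAG, float]:
    """Brute-force score maximisation by DAG enumeration (small node sets)."""
    scorer = FamilyScorer(data, score=score, ess=ess)
    best, best_score = None, -np.inf
    for dag in enumerate_dags(scorer.columns):
        s = scorer.total(dag)
        if s > best_score:
            best, best_score = dag, s
    return best, best_score


def structural_hamming_distance(a: DAG, b: DAG) -> int:
    """Edge insertions + deletions + re-orientations separating two DAGs."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("node sets differ")
    ea = {frozenset(e): e for e in a.edges()}
    eb = {frozenset(e): e for e in b.edges()}
    dist = len(set(ea) ^ set(eb))
    for pair in set(ea) & set(eb):
        if ea[pair] != eb[pair]:
            dist += 1
    return dist
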