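"""Synthetic cohort generation from a planted ground-truth Bayesian network.

The generator exists because the cohort the analysis targets (repeated
neuropsychological examinations of adults aged 70+, with adjudicated
HC / AD / NAD status) is not publicly redistributable.  It emulates:

* the three-state status marginal and the status-conditional score means
  and SDs of the reference cohort (see :mod:`cogbn.variables`),
* each test's score range and granularity (half-point PASi scores),
* status-conditional covariate prevalences (sex, ApoE4, education),
* a planted hierarchical dependency structure: an abstract-reasoning /
  naming / visual chain SIM -> BNT30 -> VRi -> VRd feeding cognitive
  status, and status driving the verbal-memory chain LMi -> LMd -> LMr and
  the paired-associate chain PASi -> PASi_h -> PASd_h.  VRr is a second
  visual input (SIM -> VRr -> VRd), which gives VRd two non-adjacent
  parents and thereby makes most edge directions identifiable from data.

Each test's continuous score is modelled through a small number of ordered
score intervals (the planted bins); within a sampled bin the raw score is
uniform on the test's scoring grid.  Participants contribute a geometric
number of examinations; scores are masked missing completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .dataset import DiscreteDataset
from .params import BNModel, CPT
from .structure import DAG
from .variables import (
    ALL_NODES,
    COVARIATE_MISSING_RATE,
    COVARIATE_PREVALENCE,
    GROUP_PROPORTIONS,
    GROUP_SCORE_STATS,
    NP_TESTS,
    STATUS,
    STATUS_STATES,
    TEST_RANGES,
    VariableSpec,
    status_spec,
)

__all__ = ["GroundTruthConfig", "default_ground_truth", "sample_cohort",
           "validate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = ["participant_id", "exam_id", *NP_TESTS, STATUS,
                  "sex", "apoe4", "education"]

#: Default number of planted score intervals per test.  Coarser than the
#: interval maps the discretizer can produce, which keeps exact inference
#: and enumeration over the 12-node network cheap while preserving the
#: group separation of the reference score distributions.
DEFAULT_LEVELS = 4

_PLANTED_EDGES = (
    ("SIM", "BNT30"), ("BNT30", "VRi"), ("SIM", "VRr"),
    ("VRi", "VRd"), ("VRr", "VRd"), ("VRd", STATUS),
    (STATUS, "LMi"), ("LMi", "LMd"), ("LMd", "LMr"),
    (STATUS, "PASi"), ("PASi", "PASi_h"), ("PASi_h", "PASd_h"),
)


@dataclass
class GroundTruthConfig:
    """Complete specification of the generating model.

    ``cpts`` are keyed by node with parent order matching the DAG's sorted
    parent tuples.  ``group_proportions`` is the target status marginal;
    the planted CPTs reproduce it by construction.
    """

    variables: list[VariableSpec]
    dag: DAG
    cpts: dict[str, CPT]
    group_proportions: tuple[float, float, float]
    covariate_prevalences: dict[str, dict[str, float]]
    covariate_missing: dict[str, float] = field(
        default_factory=lambda: dict(COVARIATE_MISSING_RATE))
    missing_rate: float = 0.05
    exams_per_participant: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.exams_per_participant < 1:
            raise ValueError("exams_per_participant must be >= 1")
        if abs(sum(self.group_proportions) - 1.0) > 1e-6:
            raise ValueError("group_proportions must sum to 1")
        names = {s.name for s in self.variables}
        if set(self.dag.nodes) != names:
            raise ValueError("DAG nodes and variable roster disagree")
        # CPT validity (row sums, parent match) enforced by CPT/BNModel
        self.model()

    def spec(self, name: str) -> VariableSpec:
        for s in self.variables:
            if s.name == name:
                return s
        raise KeyError(name)

    def model(self) -> BNModel:
        return BNModel(dag=self.dag, cpts=self.cpts,
                       variables=list(self.variables))

    def status_marginal(self) -> np.ndarray:
        """Induced P(Status), by exact enumeration over status's ancestors."""
        _, _, marginal = _conditional_upstream_tables(self)
        return marginal

    def conditional_score_mean(self, test: str, status: str) -> float:
        """E[score | status] from CPT enumeration and interval midpoints."""
        from .inference import exact_posterior

        ev = {STATUS: STATUS_STATES.index(status)}
        probs = exact_posterior(self.model(), ev, test).probs
        mids = np.array(self.spec(test).midpoints())
        return float(probs @ mids)


# ---------------------------------------------------------------------------
# Planted-model construction
# ---------------------------------------------------------------------------

def _mixture_cdf(x: float, test: str, pi: np.ndarray) -> float:
    return float(sum(
        p * norm.cdf(x, *GROUP_SCORE_STATS[test][s])
        for p, s in zip(pi, STATUS_STATES)
    ))


def _planted_intervals(test: str, n_levels: int, pi: np.ndarray
                       ) -> tuple[tuple[float, float], ...]:
    """Score intervals with boundaries at mixture quantiles, on the grid."""
    lo, hi, step = TEST_RANGES[test]
    n_grid = int(round((hi - lo) / step)) + 1
    n_levels = min(n_levels, n_grid)
    uppers: list[float] = []
    for j in range(1, n_levels):
        q = j / n_levels
        cut = brentq(lambda x: _mixture_cdf(x, test, pi) - q,
                     lo - 50.0, hi + 50.0)
        uppers.append(lo + round((cut - lo) / step) * step)
    # enforce strictly increasing uppers inside (lo - step, hi)
    for j in range(len(uppers)):
        low_ok = lo + j * step if j == 0 else uppers[j - 1] + step
        uppers[j] = max(uppers[j], low_ok)
    for j in range(len(uppers) - 1, -1, -1):
        high_ok = hi - (len(uppers) - j) * step
        uppers[j] = min(uppers[j], high_ok)
    bounds = [lo - step, *uppers, hi]
    return tuple(
        (b + step, b2) for b, b2 in zip(bounds, bounds[1:])
    )


def _level_profile(test: str, status: str,
                   intervals: tuple[tuple[float, float], ...],
                   step: float) -> np.ndarray:
    """P(bin | status): normal mass of the group's score distribution."""
    m, s = GROUP_SCORE_STATS[test][status]
    edges = [-np.inf] + [hi + step / 2 for _, hi in intervals[:-1]] + [np.inf]
    cdf = norm.cdf(edges, m, s)
    mass = np.diff(cdf)
    mass = np.clip(mass, 1e-12, None)
    return mass / mass.sum()


def _ipf(joint: np.ndarray, row_marg: np.ndarray, col_marg: np.ndarray,
         iters: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Iterative proportional fitting of a 2-D table to both margins."""
    m = joint.copy()
    for _ in range(iters):
        m *= (row_marg / np.maximum(m.sum(axis=1), 1e-300))[:, None]
        m *= (col_marg / np.maximum(m.sum(axis=0), 1e-300))[None, :]
        if abs(m.sum(axis=1) - row_marg).max() < tol:
            break
    return m


_ZBIG = 12.0  # effectively infinite on the standard-normal scale


def _z_edges(test: str, status: str,
             intervals: tuple[tuple[float, float], ...],
             step: float) -> np.ndarray:
    """Standardised bin boundaries of a test under one group's normal."""
    m, sd = GROUP_SCORE_STATS[test][status]
    cuts = [hi + step / 2 for _, hi in intervals[:-1]]
    return np.array([-_ZBIG] + [(c - m) / sd for c in cuts] + [_ZBIG])


def _gaussian_rectangles(edges: list[np.ndarray], corr: np.ndarray
                         ) -> np.ndarray:
    """Cell masses of a standard MVN over a grid of z-interval products."""
    from scipy.stats import multivariate_normal

    mvn = multivariate_normal(mean=np.zeros(len(edges)), cov=corr)
    grids = np.meshgrid(*edges, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    cdf = mvn.cdf(pts).reshape(grids[0].shape)
    mass = cdf
    for axis in range(len(edges)):
        mass = np.diff(mass, axis=axis)
    return np.clip(mass, 0.0, None)


def _pair_joint(parent: str, child: str, intervals, pi: np.ndarray,
                rho: float) -> np.ndarray:
    """Status-mixture bivariate-normal joint over (parent bin, child bin)."""
    corr = np.array([[1.0, rho], [rho, 1.0]])
    joint = np.zeros((len(intervals[parent]), len(intervals[child])))
    for w, s in zip(pi, STATUS_STATES):
        ex = _z_edges(parent, s, intervals[parent], TEST_RANGES[parent][2])
        ey = _z_edges(child, s, intervals[child], TEST_RANGES[child][2])
        joint += w * _gaussian_rectangles([ex, ey], corr)
    return joint / joint.sum()


def _row_normalise(mass: np.ndarray) -> np.ndarray:
    """Normalise the last axis into conditional rows; empty rows -> uniform."""
    r = mass.shape[-1]
    totals = mass.sum(axis=-1, keepdims=True)
    safe = np.where(totals > 1e-300, mass / np.maximum(totals, 1e-300), 1.0 / r)
    return safe.reshape(-1, r)


def default_ground_truth(missing_rate: float = 0.05,
                         exams_per_participant: float = 2.2,
                         seed: int = 0,
                         n_levels: int = DEFAULT_LEVELS,
                         edge_correlation: float = 0.7) -> GroundTruthConfig:
    """The default planted model, calibrated to the reference cohort.

    Each test has a status-conditional bin profile ``h(bin | status)``:
    the mass its group's normal score distribution places on the planted
    intervals.  Test-to-test edges follow a Gaussian-copula construction:
    within each status group the two scores are bivariate normal with
    correlation ``edge_correlation`` (the secondary VRr pathway uses a
    weaker 0.55), and the CPT is the discrete conditional of the
    pi-weighted mixture of those bivariates — so adjacent tests are
    strongly ordinally coupled, as intra-cluster test pairs are in the
    reference cohort.  Direct children of status take ``h`` as their CPT.
    The status CPT given its parent VRd is calibrated by iterative
    proportional fitting so the induced status marginal equals
    ``group_proportions`` exactly.
    """
    pi = np.asarray(GROUP_PROPORTIONS, dtype=float)
    pi = pi / pi.sum()

    intervals = {t: _planted_intervals(t, n_levels, pi) for t in NP_TESTS}
    h = {
        t: np.vstack([
            _level_profile(t, s, intervals[t], TEST_RANGES[t][2])
            for s in STATUS_STATES
        ])
        for t in NP_TESTS
    }  # h[t][status_idx, bin]

    dag = DAG(ALL_NODES, _PLANTED_EDGES)
    cards = {t: len(intervals[t]) for t in NP_TESTS}
    cards[STATUS] = len(STATUS_STATES)
    cpts: dict[str, CPT] = {}

    def make_cpt(node: str, table: np.ndarray) -> None:
        parents = dag.parents(node)
        cpts[node] = CPT(node=node, parents=parents,
                         parent_cards=tuple(cards[p] for p in parents),
                         table=table)

    rho = edge_correlation
    rho_vrr = 0.55  # secondary visual pathway SIM -> VRr -> VRd

    def copula_cpt(parent: str, child: str, r: float) -> np.ndarray:
        return _row_normalise(_pair_joint(parent, child, intervals, pi, r))

    # --- root and the chain upstream of status ----------------------------
    make_cpt("SIM", (pi @ h["SIM"])[None, :])
    make_cpt("BNT30", copula_cpt("SIM", "BNT30", rho))
    make_cpt("VRi", copula_cpt("BNT30", "VRi", rho))
    make_cpt("VRr", copula_cpt("SIM", "VRr", rho_vrr))

    # VRd has two parents (VRi, VRr, in sorted order); its CPT is the
    # discrete conditional of a mixture trivariate normal in which the
    # parents are conditionally independent given the child's latent score.
    corr3 = np.array([
        [1.0, rho * rho_vrr, rho],
        [rho * rho_vrr, 1.0, rho_vrr],
        [rho, rho_vrr, 1.0],
    ])  # order: VRi, VRr, VRd
    mass3 = np.zeros((cards["VRi"], cards["VRr"], cards["VRd"]))
    for w, s in zip(pi, STATUS_STATES):
        edges3 = [
            _z_edges("VRi", s, intervals["VRi"], TEST_RANGES["VRi"][2]),
            _z_edges("VRr", s, intervals["VRr"], TEST_RANGES["VRr"][2]),
            _z_edges("VRd", s, intervals["VRd"], TEST_RANGES["VRd"][2]),
        ]
        mass3 += w * _gaussian_rectangles(edges3, corr3)
    make_cpt("VRd", _row_normalise(mass3))

    # --- status: IPF so the induced marginal hits the target --------------
    p_sim = cpts["SIM"].table[0]
    p_bnt_given_sim = cpts["BNT30"].table
    p_vri_given_bnt = cpts["VRi"].table
    p_vrr_given_sim = cpts["VRr"].table
    # joint of the two VRd parents, marginalising SIM and BNT30
    joint_vri_vrr = np.zeros((cards["VRi"], cards["VRr"]))
    for i_sim in range(cards["SIM"]):
        p_vri = p_sim[i_sim] * (p_bnt_given_sim[i_sim] @ p_vri_given_bnt)
        joint_vri_vrr += np.outer(p_vri, p_vrr_given_sim[i_sim])
    p_vrd = np.zeros(cards["VRd"])
    t_vrd = cpts["VRd"].table
    for i, j in np.ndindex(*joint_vri_vrr.shape):
        p_vrd += joint_vri_vrr[i, j] * t_vrd[i * cards["VRr"] + j]

    c0 = pi[None, :] * h["VRd"].T  # (vrd bins, status) naive joint
    joint = _ipf(c0 * (p_vrd / np.maximum(c0.sum(axis=1), 1e-300))[:, None],
                 row_marg=p_vrd, col_marg=pi)
    make_cpt(STATUS, joint / joint.sum(axis=1, keepdims=True))

    # --- downstream of status --------------------------------------------
    cond: dict[str, np.ndarray] = {}  # induced P(node bin | status), (3, r)

    def chain_child(child: str, parent: str) -> None:
        if parent == STATUS:
            table = h[child]
            cond[child] = h[child]
        else:
            table = copula_cpt(parent, child, rho)
            cond[child] = cond[parent] @ table
        make_cpt(child, table)

    chain_child("LMi", STATUS)
    chain_child("LMd", "LMi")
    chain_child("LMr", "LMd")
    chain_child("PASi", STATUS)
    chain_child("PASi_h", "PASi")
    chain_child("PASd_h", "PASi_h")

    variables = [
        VariableSpec(name=t, kind="np_test", levels=intervals[t],
                     score_step=TEST_RANGES[t][2])
        for t in NP_TESTS
    ] + [status_spec()]

    return GroundTruthConfig(
        variables=variables,
        dag=dag,
        cpts=cpts,
        group_proportions=tuple(pi),
        covariate_prevalences={k: dict(v) for k, v in
                               COVARIATE_PREVALENCE.items()},
        missing_rate=missing_rate,
        exams_per_participant=exams_per_participant,
        seed=seed,
    )


def random_model(n_nodes: int, seed: int, max_card: int = 3,
                 max_parents: int = 2, concentration: float = 0.5
                 ) -> BNModel:
    """A random discrete Bayesian network (benchmark/oracle utility).

    Nodes get 2..``max_card`` states, a random DAG with up to
    ``max_parents`` parents per node, and Dirichlet(``concentration``)
    CPT rows — a low concentration gives peaked, informative tables.
    """
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    cards = {v: int(rng.integers(2, max_card + 1)) for v in names}
    order = list(names)
    rng.shuffle(order)
    dag = DAG(names)
    for i, v in enumerate(order):
        preds = order[:i]
        if preds:
            k = int(rng.integers(0, min(max_parents, len(preds)) + 1))
            for p in rng.choice(preds, size=k, replace=False):
                dag.add_edge(str(p), v)
    cpts = {}
    for v in names:
        parents = dag.parents(v)
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        table = rng.dirichlet([concentration] * cards[v], size=q)
        cpts[v] = CPT(node=v, parents=parents,
                      parent_cards=tuple(cards[p] for p in parents),
                      table=table)
    return BNModel(dag=dag, cpts=cpts)


#: The five cognitive-function families of the battery.
FUNCTION_BLOCKS = (
    ("LMi", "LMd", "LMr"),          # verbal memory
    ("VRi", "VRd", "VRr"),          # visual memory
    ("PASi", "PASi_h", "PASd_h"),   # new learning
    ("SIM",),                       # abstract reasoning
    ("BNT30",),                     # language / naming
)


def block_ground_truth(rho_within: float = 0.95,
                       n_levels: int = 8,
                       missing_rate: float = 0.0,
                       seed: int = 0) -> GroundTruthConfig:
    """A planted model with five near-independent cognitive-function blocks.

    Each multi-test block is a star rooted at its first test with strong
    within-block copula correlation ``rho_within``; blocks share no edges
    and status is parentless.  Raw-score correlations are therefore high
    within blocks and near zero between them — the block structure the
    correlation-cluster extraction is expected to recover.  Finer planted
    bins (``n_levels``) keep the binning attenuation of the raw-score
    correlation small.
    """
    pi = np.asarray(GROUP_PROPORTIONS, dtype=float)
    pi = pi / pi.sum()
    intervals = {t: _planted_intervals(t, n_levels, pi) for t in NP_TESTS}
    edges = []
    for block in FUNCTION_BLOCKS:
        root = block[0]
        edges.extend((root, other) for other in block[1:])
    dag = DAG(ALL_NODES, edges)
    cards = {t: len(intervals[t]) for t in NP_TESTS}
    cards[STATUS] = len(STATUS_STATES)
    cpts: dict[str, CPT] = {}

    def make_cpt(node: str, table: np.ndarray) -> None:
        parents = dag.parents(node)
        cpts[node] = CPT(node=node, parents=parents,
                         parent_cards=tuple(cards[p] for p in parents),
                         table=table)

    make_cpt(STATUS, pi[None, :])
    for block in FUNCTION_BLOCKS:
        root = block[0]
        root_marginal = pi @ np.vstack([
            _level_profile(root, s, intervals[root], TEST_RANGES[root][2])
            for s in STATUS_STATES
        ])
        make_cpt(root, root_marginal[None, :])
        for other in block[1:]:
            make_cpt(other, _row_normalise(
                _pair_joint(root, other, intervals, pi, rho_within)))

    variables = [
        VariableSpec(name=t, kind="np_test", levels=intervals[t],
                     score_step=TEST_RANGES[t][2])
        for t in NP_TESTS
    ] + [status_spec()]
    return GroundTruthConfig(
        variables=variables, dag=dag, cpts=cpts,
        group_proportions=tuple(pi),
        covariate_prevalences={k: dict(v) for k, v in
                               COVARIATE_PREVALENCE.items()},
        missing_rate=missing_rate, seed=seed,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _conditional_upstream_tables(config: GroundTruthConfig
                                 ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """P(upstream configuration | status) for the status node's ancestors.

    Enumerates the joint over the ancestors of status and Bayes-inverts it,
    so examinations of a participant can be drawn exactly from the model
    conditioned on the participant's status.  Also returns the induced
    status marginal.
    """
    model = config.model()
    anc = sorted(config.dag.ancestors(STATUS),
                 key=model.topological_order().index)
    cards = model.cards
    shapes = [cards[a] for a in anc]
    n_conf = int(np.prod(shapes)) if anc else 1
    probs = np.zeros((len(STATUS_STATES), n_conf))
    status_cpt = model.cpts[STATUS]
    for rank, conf in enumerate(np.ndindex(*shapes)):
        assign = dict(zip(anc, conf))
        p = 1.0
        for a in anc:
            cpt = model.cpts[a]
            p *= cpt.row([assign[q] for q in cpt.parents])[assign[a]]
        p_status = status_cpt.row([assign[q] for q in status_cpt.parents])
        probs[:, rank] = p * p_status
    marginal = probs.sum(axis=1)
    probs = probs / marginal[:, None]
    return anc, probs, marginal


def sample_cohort(config: GroundTruthConfig, n_exams: int,
                  seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort table of ``n_exams`` examination rows.

    Participants receive geometric examination counts (mean
    ``exams_per_participant``) and a status drawn from the model's induced
    status marginal; each of their examinations is an independent draw from
    the network conditioned on that status.  Sampled bins are converted to
    raw scores uniformly over the bin's scoring grid, covariates follow the
    status-conditional prevalences, and scores are masked missing
    completely at random at ``missing_rate``.
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    rng = np.random.default_rng(seed)
    model = config.model()
    order = model.topological_order()
    cards = model.cards

    # participant structure
    p_geo = 1.0 / config.exams_per_participant
    counts: list[int] = []
    while sum(counts) < n_exams:
        counts.extend(rng.geometric(p_geo, size=256).tolist())
    pid = np.repeat(np.arange(1, len(counts) + 1),
                    counts)[:n_exams]
    exam_id = np.concatenate([np.arange(1, c + 1) for c in counts])[:n_exams]

    # participant status, shared across a participant's examinations
    status_marg = config.status_marginal()
    part_status = rng.choice(len(STATUS_STATES), size=len(counts),
                             p=status_marg)
    status = np.repeat(part_status, counts)[:n_exams]

    # upstream ancestors of status: exact conditional draw given status
    anc, cond_tables, _ = _conditional_upstream_tables(config)
    shapes = [cards[a] for a in anc]
    ranks = np.empty(n_exams, dtype=np.int64)
    for s in range(len(STATUS_STATES)):
        mask = status == s
        if mask.any():
            ranks[mask] = rng.choice(cond_tables.shape[1], size=int(mask.sum()),
                                     p=cond_tables[s])
    states: dict[str, np.ndarray] = {}
    rem = ranks
    for a, card in zip(reversed(anc), reversed(shapes)):
        states[a] = rem % card
        rem = rem // card
    states[STATUS] = status

    # downstream: forward sampling from the CPTs
    from .inference import _draw_rows

    for v in order:
        if v in states:
            continue
        cpt = model.cpts[v]
        idx = np.zeros(n_exams, dtype=np.int64)
        for card, p in zip(cpt.parent_cards, cpt.parents):
            idx = idx * card + states[p]
        states[v] = _draw_rows(cpt.table[idx], rng)

    # bins -> raw scores, uniform over the in-bin scoring grid
    table = pd.DataFrame({"participant_id": pid, "exam_id": exam_id})
    for t in NP_TESTS:
        spec = config.spec(t)
        step = spec.score_step
        los = np.array([iv[0] for iv in spec.levels])
        n_grid = np.array([
            int(round((hi - lo) / step)) + 1 for lo, hi in spec.levels
        ])
        offsets = rng.integers(0, n_grid[states[t]])
        scores = los[states[t]] + offsets * step
        if config.missing_rate > 0:
            mask = rng.random(n_exams) < config.missing_rate
            scores = scores.astype(float)
            scores[mask] = np.nan
        table[t] = scores
    table[STATUS] = np.array(STATUS_STATES)[states[STATUS]]

    # covariates from status-conditional prevalences
    prev = config.covariate_prevalences
    p_male = np.array([prev["male"][s] for s in STATUS_STATES])[states[STATUS]]
    table["sex"] = np.where(rng.random(n_exams) < p_male, "M", "F")
    p_apoe = np.array([prev["apoe4_pos"][s]
                       for s in STATUS_STATES])[states[STATUS]]
    apoe = np.where(rng.random(n_exams) < p_apoe, "+", "-").astype(object)
    apoe[rng.random(n_exams) < config.covariate_missing.get("apoe4", 0.0)] = None
    table["apoe4"] = apoe
    p_edu = np.array([prev["educ_high"][s]
                      for s in STATUS_STATES])[states[STATUS]]
    edu = np.where(rng.random(n_exams) < p_edu, "high", "low").astype(object)
    edu[rng.random(n_exams) < config.covariate_missing.get("education", 0.0)] = None
    table["education"] = edu
    return table


def validate_cohort(table: pd.DataFrame, config: GroundTruthConfig) -> None:
    """Check scores against ranges and grids; status must never be missing."""
    missing_cols = set(COHORT_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {sorted(missing_cols)}")
    if table[STATUS].isna().any():
        raise ValueError("status must never be missing")
    bad_status = set(table[STATUS].unique()) - set(STATUS_STATES)
    if bad_status:
        raise ValueError(f"unknown status labels {sorted(bad_status)}")
    for t in NP_TESTS:
        spec = config.spec(t)
        vals = table[t].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        if vals.min() < spec.min_score - 1e-9 or vals.max() > spec.max_score + 1e-9:
            raise ValueError(f"{t}: scores outside [{spec.min_score}, "
                             f"{spec.max_score}]")
        frac = (vals - spec.min_score) / spec.score_step
        if np.abs(frac - np.round(frac)).max() > 1e-6:
            raise ValueError(f"{t}: scores off the {spec.score_step} grid")
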