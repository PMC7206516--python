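"""Cross-validated diagnostic evaluation and stratified sub-analyses.

The pipeline per training fold mirrors the full analysis: discretize,
learn an averaged network by bootstrap, estimate CPTs, then diagnose each
held-out examination from its observed test bins by averaged
likelihood-weighting inference.  Performance is the pooled 3-class
confusion matrix, overall accuracy, and a binary sensitivity/specificity
in which any dementia (AD or NAD) is the positive class and HC the
negative (an AD-vs-rest collapse is available by configuration).

Stratified analyses repeat the learn + blanket (+ CV) pipeline within
levels of sex, ApoE4 carrier status or education, after excluding rows
missing the stratifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .blanket import BlanketReport, markov_blanket
from .dataset import MISSING, DiscreteDataset
from .discretize import DiscretizationMap, apply_discretization, fit_discretization
from .inference import predict_status
from .params import fit_bayes, fit_mle
from .structure import DAG, EdgeSupport, bootstrap_average, hill_climb
from .variables import NP_TESTS, STATUS, STATUS_STATES

__all__ = ["CVConfig", "CVReport", "StratifiedResult", "confusion_metrics",
           "cross_validate", "stratified_networks", "first_precursors"]


@dataclass
class CVConfig:
    """Settings for the end-to-end cross-validated pipeline.

    Discretization scope ``fold`` refits interval maps inside each
    training fold (leakage-safe, the default); ``global`` fits once on all
    rows; ``planted`` uses a provided map (e.g. the generator's own bins).
    """

    folds: int = 10
    discretization_scope: str = "fold"   # fold | global | planted
    k_max: int = 10
    dmap: DiscretizationMap | None = None
    bootstrap_B: int = 25
    strength_threshold: float = 0.5
    search_restarts: int = 0
    estimator: str = "bayes"             # bayes | mle
    iss: float = 1.0
    inference_method: str = "lw"         # lw | exact
    repeats: int = 10
    n_samples: int = 500
    binarization: str = "dementia_vs_hc"  # dementia_vs_hc | ad_vs_rest
    group_by_participant: bool = False

    def snapshot(self) -> dict:
        d = asdict(self)
        d["dmap"] = None if self.dmap is None else "provided"
        return d


@dataclass
class CVReport:
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    per_fold: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold": self.per_fold,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVReport":
        conf = pd.DataFrame(d["confusion"]).loc[
            list(STATUS_STATES), list(STATUS_STATES)]
        return cls(confusion=conf, accuracy=d["accuracy"],
                   sensitivity=d["sensitivity"],
                   specificity=d["specificity"],
                   per_fold=d.get("per_fold", []),
                   config=d.get("config", {}))


def confusion_metrics(predictions, truths,
                      binarization: str = "dementia_vs_hc"
                      ) -> tuple[pd.DataFrame, float, float | None, float | None]:
    """3-class confusion matrix and derived rates.

    Rows are the true status, columns the predicted status.  Accuracy is
    the trace over the total.  For the binary collapse, the positive class
    is {AD, NAD} (or {AD} under ``ad_vs_rest``); sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), reported as None when the corresponding
    class is empty.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    bad = set(predictions) | set(truths)
    if bad - set(STATUS_STATES):
        raise ValueError(
            f"labels outside {STATUS_STATES}: {sorted(bad - set(STATUS_STATES))}")
    conf = pd.DataFrame(0, index=list(STATUS_STATES),
                        columns=list(STATUS_STATES))
    for t, p in zip(truths, predictions):
        conf.at[t, p] += 1
    total = conf.to_numpy().sum()
    accuracy = float(np.trace(conf.to_numpy()) / total)
    if binarization == "dementia_vs_hc":
        positive = {"AD", "NAD"}
    elif binarization == "ad_vs_rest":
        positive = {"AD"}
    else:
        raise ValueError(f"unknown binarization {binarization!r}")
    tp = fn = tn = fp = 0
    for t, p in zip(truths, predictions):
        if t in positive:
            tp += p in positive
            fn += p not in positive
        else:
            tn += p not in positive
            fp += p in positive
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    return conf, accuracy, sensitivity, specificity


def _stratified_folds(labels: np.ndarray, groups: np.ndarray | None,
                      folds: int, seed: int):
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    if groups is None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        return list(splitter.split(np.zeros(len(labels)), labels))
    splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                    random_state=seed)
    return list(splitter.split(np.zeros(len(labels)), labels, groups))


def _evidence_from_row(row: pd.Series, dmap: DiscretizationMap) -> dict:
    ev = {}
    for var in dmap.intervals:
        val = row[var]
        if pd.isna(val):
            continue
        try:
            ev[var] = dmap.bin_index(var, float(val))
        except ValueError:
            # score outside the training fold's interval table: the
            # examination is diagnosed without that test
            continue
    return ev


def cross_validate(table: pd.DataFrame, config: CVConfig | None = None,
                   seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validated diagnosis of examination rows."""
    config = config or CVConfig()
    counts = table[STATUS].value_counts()
    for s in STATUS_STATES:
        if counts.get(s, 0) < config.folds:
            raise ValueError(
                f"status class {s} has {counts.get(s, 0)} rows; "
                f"need >= {config.folds} to build {config.folds} folds"
            )
    labels = table[STATUS].to_numpy()
    groups = (table["participant_id"].to_numpy()
              if config.group_by_participant else None)
    rng = np.random.default_rng(seed)
    global_map = None
    if config.discretization_scope == "global":
        global_map = fit_discretization(table, k_max=config.k_max)
    elif config.discretization_scope == "planted":
        if config.dmap is None:
            raise ValueError("planted scope requires config.dmap")
        global_map = config.dmap
    elif config.discretization_scope != "fold":
        raise ValueError(
            f"unknown discretization scope {config.discretization_scope!r}")

    all_pred: list[str] = []
    all_truth: list[str] = []
    per_fold = []
    for fold_id, (train_idx, test_idx) in enumerate(
        _stratified_folds(labels, groups, config.folds, seed)
    ):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        dmap = (global_map if global_map is not None
                else fit_discretization(train, k_max=config.k_max))
        train_data = apply_discretization(train, dmap)
        _, dag = bootstrap_average(
            train_data,
            learner=lambda d, s: hill_climb(
                d, restarts=config.search_restarts, seed=s),
            B=config.bootstrap_B,
            strength_threshold=config.strength_threshold,
            seed=fold_seed,
        )
        if config.estimator == "mle":
            model = fit_mle(dag, train_data)
        else:
            model = fit_bayes(dag, train_data, iss=config.iss)
        preds = []
        for i, (_, row) in enumerate(test.iterrows()):
            ev = _evidence_from_row(row, dmap)
            label, _, _ = predict_status(
                model, ev, repeats=config.repeats,
                n_samples=config.n_samples,
                seed=fold_seed + i + 1,
                method=config.inference_method,
            )
            preds.append(label)
        truth = test[STATUS].tolist()
        all_pred.extend(preds)
        all_truth.extend(truth)
        _, fold_acc, _, _ = confusion_metrics(preds, truth,
                                              config.binarization)
        per_fold.append({
            "fold": fold_id,
            "seed": fold_seed,
            "n_test": len(test),
            "accuracy": fold_acc,
            "edges": dag.edges(),
        })
    conf, acc, sens, spec = confusion_metrics(all_pred, all_truth,
                                              config.binarization)
    return CVReport(confusion=conf, accuracy=acc, sensitivity=sens,
                    specificity=spec, per_fold=per_fold,
                    config=config.snapshot())


# ---------------------------------------------------------------------------
# Stratified analyses
# ---------------------------------------------------------------------------

def first_precursors(dag: DAG, target: str = STATUS) -> list[str]:
    """Ancestors of the target at maximal depth (the chain's entry points).

    Depth is the longest directed path length to the target; the deepest
    ancestors are the first precursors in the hierarchy.
    """
    import networkx as nx

    g = dag.to_networkx()
    anc = nx.ancestors(g, target)
    if not anc:
        return []
    depth = {
        a: max(len(p) - 1 for p in nx.all_simple_paths(g, a, target))
        for a in anc
    }
    top = max(depth.values())
    return sorted(a for a, d in depth.items() if d == top)


@dataclass
class StratifiedResult:
    stratum: str
    n_rows: int
    excluded: dict
    dag: DAG | None = None
    support: EdgeSupport | None = None
    blanket: BlanketReport | None = None
    cv: CVReport | None = None
    precursors: list = field(default_factory=list)
    skipped_reason: str | None = None


_STRATA_LEVELS = {
    "sex": ("M", "F"),
    "apoe4": ("+", "-"),
    "education": ("high", "low"),
}


def stratified_networks(table: pd.DataFrame, strata: str,
                        config: CVConfig | None = None, seed: int = 0,
                        run_cv: bool = True) -> list[StratifiedResult]:
    """Per-stratum learn + blanket (+ CV) pipeline.

    Rows missing the stratifier are excluded (counted in the result); a
    stratum without enough rows per status class is skipped with a reason
    rather than failing the whole analysis.
    """
    if strata not in _STRATA_LEVELS:
        raise ValueError(f"unknown stratifier {strata!r}")
    config = config or CVConfig()
    present = table[~table[strata].isna()]
    n_excluded = len(table) - len(present)
    rng = np.random.default_rng(seed)
    results = []
    for level in _STRATA_LEVELS[strata]:
        sub = present[present[strata] == level]
        stratum_seed = int(rng.integers(0, 2**31 - 1))
        base = {
            "stratum": f"{strata}={level}",
            "n_rows": len(sub),
            "excluded": {"missing_stratifier": n_excluded},
        }
        counts = sub[STATUS].value_counts() if len(sub) else {}
        too_small = [
            s for s in STATUS_STATES
            if (counts.get(s, 0) if len(sub) else 0) < max(config.folds, 10)
        ]
        if len(sub) == 0 or too_small:
            results.append(StratifiedResult(
                **base,
                skipped_reason=(
                    "no rows in stratum" if len(sub) == 0 else
                    f"status classes {too_small} below minimum size"
                ),
            ))
            continue
        dmap = (config.dmap if config.discretization_scope == "planted"
                else fit_discretization(sub, k_max=config.k_max))
        data = apply_discretization(sub, dmap)
        support, dag = bootstrap_average(
            data,
            learner=lambda d, s: hill_climb(
                d, restarts=config.search_restarts, seed=s),
            B=config.bootstrap_B,
            strength_threshold=config.strength_threshold,
            seed=stratum_seed,
        )
        report = markov_blanket(dag, STATUS)
        cv = cross_validate(sub, config, seed=stratum_seed) if run_cv else None
        results.append(StratifiedResult(
            **base, dag=dag, support=support, blanket=report, cv=cv,
            precursors=first_precursors(dag, STATUS),
        ))
    return results
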