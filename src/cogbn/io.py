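"""Readers, writers, pipeline configuration and the end-to-end pipeline.

CSV dialect for cohort tables: comma-separated, UTF-8, "." decimal, empty
field = missing.  The pipeline runs the stages in analysis order —
simulate/load, discretize, correlate, learn structure, estimate
parameters, blanket, cross-validate — writing every artifact plus a
manifest of stage seeds and content hashes so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blanket import ci_table, markov_blanket
from .correlation import correlation_matrix, extract_clusters
from .discretize import DiscretizationMap, apply_discretization, fit_discretization
from .evaluate import CVConfig, cross_validate
from .params import BNModel, CPT, fit_bayes, fit_mle
from .structure import DAG, EdgeSupport, bootstrap_average, hill_climb, tabu_search
from .synth import default_ground_truth, sample_cohort, validate_cohort
from .variables import STATUS, STATUS_STATES, TEST_RANGES

__all__ = [
    "PipelineConfig", "PipelineStageError",
    "read_cohort_csv", "write_cohort_csv",
    "dag_to_dot", "dag_to_json", "dag_from_json",
    "model_to_json", "model_from_json",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def read_cohort_csv(path, roster: dict | None = None) -> pd.DataFrame:
    """Read and validate a cohort table.

    ``roster`` maps test name -> (min, max, step); defaults to the
    standard 11-test battery.  Out-of-range or off-grid scores raise a
    parse error naming the line (1-based, counting the header as line 1).
    """
    roster = roster or TEST_RANGES
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"{path}: empty cohort file")
    missing_cols = [c for c in ["participant_id", "exam_id", STATUS]
                    if c not in table.columns]
    missing_cols += [t for t in roster if t not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if table[STATUS].isna().any():
        line = int(table[STATUS].isna().idxmax()) + 2
        raise ValueError(f"{path}:{line}: missing status")
    bad_status = ~table[STATUS].isin(STATUS_STATES)
    if bad_status.any():
        line = int(bad_status.idxmax()) + 2
        raise ValueError(
            f"{path}:{line}: unknown status {table[STATUS][bad_status].iloc[0]!r}")
    for t, (lo, hi, step) in roster.items():
        vals = pd.to_numeric(table[t], errors="coerce")
        bad = vals.notna() & ((vals < lo - 1e-9) | (vals > hi + 1e-9))
        frac = (vals - lo) / step
        bad |= vals.notna() & (np.abs(frac - np.round(frac)) > 1e-6)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}:{line}: {t}={vals[bad].iloc[0]} outside "
                f"[{lo}, {hi}] step {step}")
        table[t] = vals
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Graph / model serialization
# ---------------------------------------------------------------------------

def dag_to_dot(dag: DAG, support: EdgeSupport | None = None) -> str:
    lines = ["digraph G {"]
    for v in dag.nodes:
        lines.append(f'  "{v}";')
    for u, v in dag.edges():
        if support is not None:
            lines.append(f'  "{u}" -> "{v}" [label="{support.strength(u, v):.2f}"];')
        else:
            lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def dag_to_json(dag: DAG) -> str:
    return json.dumps({"nodes": list(dag.nodes), "edges": dag.edges()},
                      indent=2)


def dag_from_json(text: str) -> DAG:
    raw = json.loads(text)
    return DAG(raw["nodes"], [tuple(e) for e in raw["edges"]])


def model_to_json(model: BNModel) -> str:
    return json.dumps({
        "nodes": list(model.nodes),
        "edges": model.dag.edges(),
        "cpts": {
            v: {
                "parents": list(model.cpts[v].parents),
                "parent_cards": list(model.cpts[v].parent_cards),
                "table": model.cpts[v].table.tolist(),
            }
            for v in model.nodes
        },
    }, indent=2)


def model_from_json(text: str) -> BNModel:
    raw = json.loads(text)
    dag = DAG(raw["nodes"], [tuple(e) for e in raw["edges"]])
    cpts = {
        v: CPT(node=v, parents=tuple(c["parents"]),
               parent_cards=tuple(c["parent_cards"]),
               table=np.array(c["table"]))
        for v, c in raw["cpts"].items()
    }
    return BNModel(dag=dag, cpts=cpts)


def cpts_to_csv(model: BNModel) -> pd.DataFrame:
    """Long-format CPT export: node, parent configuration, state, prob."""
    rows = []
    for v in model.nodes:
        cpt = model.cpts[v]
        shapes = cpt.parent_cards if cpt.parents else ()
        for j in range(cpt.table.shape[0]):
            conf = []
            rem = j
            for card in reversed(shapes):
                conf.append(rem % card)
                rem //= card
            conf = tuple(reversed(conf))
            conf_str = ";".join(
                f"{p}={s}" for p, s in zip(cpt.parents, conf)) or "-"
            for k in range(cpt.cardinality):
                rows.append({"node": v, "parent_config": conf_str,
                             "state": k, "probability": cpt.table[j, k]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative configuration of the full analysis (YAML-serializable)."""

    input_path: str | None = None      # None -> simulate a cohort
    n_exams: int = 4512
    missing_rate: float = 0.05
    k_max: int = 10
    discretization_scope: str = "global"
    score: str = "bic"
    search: str = "hill_climb"         # hill_climb | tabu
    restarts: int = 5
    tabu_len: int = 10
    bootstrap_B: int = 500
    strength_threshold: float = 0.5
    estimator: str = "bayes"
    iss: float = 1.0
    n_samples: int = 5000
    repeats: int = 100
    cv_folds: int = 10
    cv_binarization: str = "dementia_vs_hc"
    cv_group_by_participant: bool = False
    cv_bootstrap_B: int = 25
    cv_repeats: int = 10
    cv_n_samples: int = 500
    seed: int = 0
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name in ("n_exams", "k_max", "bootstrap_B", "n_samples",
                     "repeats", "cv_folds", "cv_bootstrap_B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a master seed is required")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def cv_config(self, dmap: DiscretizationMap | None = None) -> CVConfig:
        return CVConfig(
            folds=self.cv_folds,
            discretization_scope=self.discretization_scope
            if self.discretization_scope in ("fold", "global") else "fold",
            k_max=self.k_max,
            dmap=dmap,
            bootstrap_B=self.cv_bootstrap_B,
            strength_threshold=self.strength_threshold,
            estimator=self.estimator,
            iss=self.iss,
            repeats=self.cv_repeats,
            n_samples=self.cv_n_samples,
            binarization=self.cv_binarization,
            group_by_participant=self.cv_group_by_participant,
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage_seeds(master: int, stages: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).generate_state(len(stages))
    return {s: int(v % (2**31)) for s, v in zip(stages, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_STAGES = ["simulate", "discretize", "correlate", "learn", "fit",
           "blanket", "crossval"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in analysis order; returns the manifest dict.

    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage.  The manifest records the derived per-stage seeds and the
    sha256 of every artifact, so re-running the same config and seed
    reproduces identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, _STAGES)
    artifacts: dict[str, str] = {}

    def save(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        artifacts[name] = _sha256(p)

    stage = "simulate"
    try:
        if config.input_path is None:
            gt = default_ground_truth(missing_rate=config.missing_rate)
            cohort = sample_cohort(gt, config.n_exams, seed=seeds["simulate"])
            validate_cohort(cohort, gt)
        else:
            cohort = read_cohort_csv(config.input_path)
        write_cohort_csv(cohort, out / "cohort.csv")
        artifacts["cohort.csv"] = _sha256(out / "cohort.csv")

        stage = "discretize"
        dmap = fit_discretization(cohort, k_max=config.k_max)
        save("discretization.json", dmap.to_json())
        save("discretization.txt", dmap.to_text())
        data = apply_discretization(cohort, dmap)

        stage = "correlate"
        report = correlation_matrix(cohort)
        report.matrix.to_csv(out / "correlation.csv")
        artifacts["correlation.csv"] = _sha256(out / "correlation.csv")
        clusters = extract_clusters(report.matrix)
        save("clusters.json", json.dumps({"cutoff": report.cutoff,
                                          "clusters": clusters}, indent=2))

        stage = "learn"
        if config.search == "tabu":
            def learner(d, s):
                return tabu_search(d, tabu_len=config.tabu_len, seed=s)
        else:
            def learner(d, s):
                return hill_climb(d, restarts=config.restarts, seed=s,
                                  score=config.score)
        support, dag = bootstrap_average(
            data, learner=learner, B=config.bootstrap_B,
            strength_threshold=config.strength_threshold,
            seed=seeds["learn"])
        save("network.json", dag_to_json(dag))
        save("network.dot", dag_to_dot(dag, support))
        support.to_frame().to_csv(out / "edge_support.csv", index=False)
        artifacts["edge_support.csv"] = _sha256(out / "edge_support.csv")

        stage = "fit"
        if config.estimator == "mle":
            model = fit_mle(dag, data)
        else:
            model = fit_bayes(dag, data, iss=config.iss)
        save("model.json", model_to_json(model))
        cpts_to_csv(model).to_csv(out / "cpts.csv", index=False)
        artifacts["cpts.csv"] = _sha256(out / "cpts.csv")

        stage = "blanket"
        blanket = markov_blanket(dag, STATUS)
        save("blanket.json", json.dumps(blanket.to_dict(), indent=2))
        ci = ci_table(data)
        ci.to_csv(out / "ci_table.csv")
        artifacts["ci_table.csv"] = _sha256(out / "ci_table.csv")

        stage = "crossval"
        cv = cross_validate(cohort, config.cv_config(dmap),
                            seed=seeds["crossval"])
        save("cv_report.json", json.dumps(cv.to_dict(), indent=2))
        cv.confusion.to_csv(out / "confusion.csv")
        artifacts["confusion.csv"] = _sha256(out / "confusion.csv")
    except Exception as exc:  # noqa: BLE001 - stage context matters
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
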