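"""Variable roster for the neuropsychological (NP) battery and cognitive status.

The analysis models 11 NP tests plus a three-state cognitive status
(healthy control HC, Alzheimer disease AD, non-Alzheimer dementia NAD).
Each NP test is a bounded discrete-valued score: most are integer scored,
Paired Associate Learning Immediate Recall (PASi) is scored in half points.

The module also houses the reference cohort characteristics used to
calibrate the synthetic-cohort generator: status group sizes, per-group
score means and standard deviations, and covariate prevalences observed
in a large community-based study of adults aged 70 and older.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

STATUS = "Status"
STATUS_STATES: tuple[str, ...] = ("HC", "AD", "NAD")

#: The 11 NP tests, in canonical order.
#: LM{i,d,r}: Logical Memory immediate/delayed recall, recognition.
#: VR{i,d,r}: Visual Reproductions immediate/delayed recall, recognition.
#: PASi: Paired Associate Learning immediate recall (half-point scored);
#: PASi_h / PASd_h: its hard-pair immediate / delayed subscores.
#: SIM: WAIS Similarities; BNT30: Boston Naming Test, 30-item even version.
NP_TESTS: tuple[str, ...] = (
    "LMi", "LMd", "LMr",
    "VRi", "VRd", "VRr",
    "PASi", "PASi_h", "PASd_h",
    "SIM", "BNT30",
)

ALL_NODES: tuple[str, ...] = NP_TESTS + (STATUS,)

COVARIATES: tuple[str, ...] = ("sex", "apoe4", "education")

#: (min score, max score, scoring granularity) per test.
TEST_RANGES: dict[str, tuple[float, float, float]] = {
    "LMi": (0.0, 23.0, 1.0),
    "LMd": (0.0, 24.0, 1.0),
    "LMr": (0.0, 11.0, 1.0),
    "VRi": (0.0, 14.0, 1.0),
    "VRd": (0.0, 14.0, 1.0),
    "VRr": (0.0, 4.0, 1.0),
    "PASi": (0.0, 21.0, 0.5),
    "PASi_h": (0.0, 12.0, 1.0),
    "PASd_h": (0.0, 4.0, 1.0),
    "SIM": (0.0, 26.0, 1.0),
    "BNT30": (0.0, 30.0, 1.0),
}

# ---------------------------------------------------------------------------
# Reference cohort calibration (community-based sample, ages 70+):
# 4512 NP examinations contributed by 2091 participants.
# ---------------------------------------------------------------------------

REFERENCE_N_EXAMS = 4512
REFERENCE_N_PARTICIPANTS = 2091

#: Examination counts by cognitive status (HC, AD, NAD).
GROUP_COUNTS: dict[str, int] = {"HC": 3514, "AD": 555, "NAD": 443}

#: Status marginal implied by the group counts.
GROUP_PROPORTIONS: tuple[float, float, float] = tuple(
    round(GROUP_COUNTS[s] / REFERENCE_N_EXAMS, 3) for s in STATUS_STATES
)  # (0.779, 0.123, 0.098)

#: Per-test (mean, SD) of the raw score within each status group.
GROUP_SCORE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "LMi":    {"HC": (11.2, 3.7), "AD": (4.8, 3.8), "NAD": (7.9, 3.9)},
    "LMd":    {"HC": (10.2, 3.9), "AD": (3.0, 4.0), "NAD": (6.5, 4.1)},
    "LMr":    {"HC": (9.4, 1.4),  "AD": (7.1, 2.3), "NAD": (8.5, 1.7)},
    "VRi":    {"HC": (7.1, 3.0),  "AD": (3.1, 2.3), "NAD": (4.0, 2.5)},
    "VRd":    {"HC": (6.1, 3.1),  "AD": (1.6, 1.9), "NAD": (2.7, 2.4)},
    "VRr":    {"HC": (2.6, 1.1),  "AD": (1.3, 1.1), "NAD": (1.7, 1.1)},
    "PASi":   {"HC": (12.8, 3.3), "AD": (8.4, 2.9), "NAD": (9.9, 2.8)},
    "PASd_h": {"HC": (2.0, 1.3),  "AD": (0.5, 0.9), "NAD": (1.0, 1.1)},
    "PASi_h": {"HC": (4.4, 3.0),  "AD": (1.1, 1.7), "NAD": (2.0, 2.0)},
    "SIM":    {"HC": (15.5, 3.9), "AD": (9.8, 5.0), "NAD": (11.6, 4.7)},
    "BNT30":  {"HC": (26.1, 3.4), "AD": (19.4, 5.9), "NAD": (22.3, 5.4)},
}

#: Status-conditional covariate prevalences: P(male), P(education beyond
#: high school), P(ApoE4 carrier), among examinations with valid data.
COVARIATE_PREVALENCE: dict[str, dict[str, float]] = {
    "male":      {"HC": 0.433, "AD": 0.323, "NAD": 0.497},
    "educ_high": {"HC": 0.575, "AD": 0.348, "NAD": 0.455},
    "apoe4_pos": {"HC": 0.171, "AD": 0.347, "NAD": 0.208},
}

#: Fraction of examinations missing each covariate (education: 11/4512;
#: ApoE4 genotype: 200/4512; sex: never missing).
COVARIATE_MISSING_RATE: dict[str, float] = {
    "sex": 0.0,
    "education": 11 / 4512,
    "apoe4": 200 / 4512,
}

VariableKind = Literal["np_test", "status", "covariate"]


@dataclass(frozen=True)
class VariableSpec:
    """A discrete modelling variable.

    For ``kind == "np_test"`` the levels are closed score intervals
    ``(lo, hi)`` in raw score units, sorted ascending, non-overlapping and
    jointly covering ``[min_score, max_score]`` on the ``score_step`` grid.
    For ``kind == "status"`` the levels are the status state names.
    """

    name: str
    kind: VariableKind
    levels: tuple
    score_step: float = 1.0

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"{self.name}: levels must be nonempty")
        if self.score_step <= 0:
            raise ValueError(f"{self.name}: score_step must be positive")
        if self.kind == "np_test":
            ivs = self.levels
            for lo, hi in ivs:
                if lo > hi:
                    raise ValueError(f"{self.name}: interval ({lo},{hi}) inverted")
            for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
                if not hi1 < lo2:
                    raise ValueError(
                        f"{self.name}: intervals ({lo1},{hi1}) and ({lo2},{hi2}) "
                        "overlap or are unsorted"
                    )
                # gaps larger than one grid step would leave scores uncovered
                if abs((lo2 - hi1) - self.score_step) > 1e-9:
                    raise ValueError(
                        f"{self.name}: gap between ({lo1},{hi1}) and ({lo2},{hi2}) "
                        f"is not one score_step ({self.score_step})"
                    )

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    @property
    def min_score(self) -> float:
        if self.kind != "np_test":
            raise AttributeError("min_score only defined for np_test variables")
        return self.levels[0][0]

    @property
    def max_score(self) -> float:
        if self.kind != "np_test":
            raise AttributeError("max_score only defined for np_test variables")
        return self.levels[-1][1]

    def midpoints(self) -> list[float]:
        """Interval midpoints in raw score units (np_test only)."""
        if self.kind != "np_test":
            raise AttributeError("midpoints only defined for np_test variables")
        return [(lo + hi) / 2.0 for lo, hi in self.levels]

    def interval_index(self, value: float) -> int:
        """0-based bin index of a raw score; raises on out-of-range values."""
        for j, (lo, hi) in enumerate(self.levels):
            if lo - 1e-9 <= value <= hi + 1e-9:
                return j
        raise ValueError(
            f"{self.name}: score {value} outside intervals {self.levels}"
        )


def status_spec() -> VariableSpec:
    return VariableSpec(name=STATUS, kind="status", levels=STATUS_STATES)


def grid_values(name: str) -> list[float]:
    """All attainable raw scores of a test on its scoring grid."""
    lo, hi, step = TEST_RANGES[name]
    n = int(round((hi - lo) / step))
    return [lo + i * step for i in range(n + 1)]


def validate_roster(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in roster")
    for s in specs:
        if s.kind == "np_test" and s.name in TEST_RANGES:
            lo, hi, step = TEST_RANGES[s.name]
            if s.min_score > lo or s.max_score < hi:
                raise ValueError(
                    f"{s.name}: levels {s.levels} do not cover [{lo},{hi}]"
                )
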