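"""Discrete dataset container shared by structure learning, estimation and
inference.

A :class:`DiscreteDataset` holds integer state codes per variable
(``-1`` marks a missing value) together with each variable's cardinality.
Status is coded in the fixed order HC=0, AD=1, NAD=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class DiscreteDataset:
    """Integer-coded observations of a set of discrete variables.

    Parameters
    ----------
    codes : pandas.DataFrame
        One column per variable, integer dtype; ``-1`` encodes missing.
    cards : dict
        Cardinality (number of states) per variable.
    passthrough : pandas.DataFrame, optional
        Columns carried alongside (ids, covariates) that are not part of
        the discrete model.
    """

    codes: pd.DataFrame
    cards: dict[str, int]
    passthrough: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in self.codes.columns:
            if col not in self.cards:
                raise ValueError(f"no cardinality given for column {col!r}")
            vals = self.codes[col].to_numpy()
            if vals.size and (vals.max(initial=MISSING) >= self.cards[col]):
                raise ValueError(
                    f"column {col!r} has codes outside [0, {self.cards[col]})"
                )

    @property
    def n_rows(self) -> int:
        return len(self.codes)

    @property
    def columns(self) -> list[str]:
        return list(self.codes.columns)

    def matrix(self, cols: list[str] | None = None) -> np.ndarray:
        """Codes as an ``(n, len(cols))`` int64 array."""
        cols = cols if cols is not None else self.columns
        return self.codes[cols].to_numpy(dtype=np.int64)

    def complete_mask(self, cols: list[str] | None = None) -> np.ndarray:
        return (self.matrix(cols) != MISSING).all(axis=1)

    def complete_cases(self, cols: list[str] | None = None) -> "DiscreteDataset":
        """Rows with no missing value among ``cols`` (default: all columns)."""
        mask = self.complete_mask(cols)
        return DiscreteDataset(
            codes=self.codes.loc[mask].reset_index(drop=True),
            cards=dict(self.cards),
            passthrough=(
                self.passthrough.loc[mask].reset_index(drop=True)
                if self.passthrough is not None
                else None
            ),
        )

    def subset(self, row_idx: np.ndarray) -> "DiscreteDataset":
        return DiscreteDataset(
            codes=self.codes.iloc[row_idx].reset_index(drop=True),
            cards=dict(self.cards),
            passthrough=(
                self.passthrough.iloc[row_idx].reset_index(drop=True)
                if self.passthrough is not None
                else None
            ),
        )


def from_arrays(arrays: dict[str, np.ndarray], cards: dict[str, int]) -> DiscreteDataset:
    return DiscreteDataset(codes=pd.DataFrame(arrays), cards=dict(cards))
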