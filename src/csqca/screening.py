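"""Individual-condition necessity and sufficiency screening.

Each condition is crossed with the outcome in a 2x2 contingency table.
Necessity consistency is the share of outcome cases that have the condition,
|X ∩ Y| / |Y|; sufficiency consistency is the share of condition cases that
have the outcome, |X ∩ Y| / |X|.  The two are dual: sufficiency of X for Y
equals necessity of Y for X.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._rounding import pct
from .dataset import Dataset, ValidationError

__all__ = [
    "ContingencyTable",
    "Thresholds",
    "ScreenResult",
    "UndefinedConsistency",
    "contingency",
    "necessity_consistency",
    "sufficiency_consistency",
    "screen_conditions",
    "screen_table",
]


class UndefinedConsistency(ArithmeticError):
    """A consistency whose denominator set is empty (reported as
    not-applicable, never coerced to 0 or 1)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of cases by (condition membership, outcome membership)."""

    n11: int  # condition 1, outcome 1
    n10: int  # condition 1, outcome 0
    n01: int  # condition 0, outcome 1
    n00: int  # condition 0, outcome 0

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class Thresholds:
    """Consistency cuts for the whole analysis.

    ``necessity_cut`` / ``sufficiency_cut`` govern individual-condition
    screening; ``row_incl_cut`` / ``row_n_cut`` govern truth-table row
    classification.  Comparisons use >= by default; ``strict=True`` switches
    to a strictly-greater reading.
    """

    necessity_cut: float = 0.90
    sufficiency_cut: float = 0.80
    row_incl_cut: float = 0.80
    row_n_cut: int = 1
    strict: bool = False

    def __post_init__(self) -> None:
        for label, v in (
            ("necessity_cut", self.necessity_cut),
            ("sufficiency_cut", self.sufficiency_cut),
            ("row_incl_cut", self.row_incl_cut),
        ):
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{label} must lie in (0, 1], got {v}")
        if self.row_n_cut < 1:
            raise ValidationError("row_n_cut must be >= 1")

    def passes(self, value: float, cut: float) -> bool:
        return value > cut if self.strict else value >= cut


@dataclass(frozen=True)
class ScreenResult:
    condition: str
    letter: str
    necessity_consistency: float
    sufficiency_consistency: float | None  # None when condition never present
    n_with_condition: int
    n_with_condition_and_outcome: int
    necessary_flag: bool
    sufficient_flag: bool


def contingency(dataset: Dataset, condition: str) -> ContingencyTable:
    """The 2x2 table crossing one condition with the outcome."""
    if condition not in dataset.condition_names:
        raise ValidationError(f"unknown condition {condition!r}")
    n11 = n10 = n01 = n00 = 0
    for case in dataset.cases:
        x, y = case.memberships[condition], case.outcome
        if x and y:
            n11 += 1
        elif x:
            n10 += 1
        elif y:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def necessity_consistency(ct: ContingencyTable) -> float:
    """|condition ∩ outcome| / |outcome|."""
    denom = ct.n11 + ct.n01
    if denom == 0:
        raise UndefinedConsistency("necessity undefined: outcome set is empty")
    return ct.n11 / denom


def sufficiency_consistency(ct: ContingencyTable) -> float:
    """|condition ∩ outcome| / |condition|."""
    denom = ct.n11 + ct.n10
    if denom == 0:
        raise UndefinedConsistency(
            "sufficiency undefined: condition never present"
        )
    return ct.n11 / denom


def screen_conditions(
    dataset: Dataset, thresholds: Thresholds | None = None
) -> list[ScreenResult]:
    """Necessity/sufficiency screen for every condition, in registry order."""
    thresholds = thresholds or Thresholds()
    results: list[ScreenResult] = []
    for cond in dataset.conditions:
        ct = contingency(dataset, cond.name)
        nec = necessity_consistency(ct)
        try:
            suf: float | None = sufficiency_consistency(ct)
        except UndefinedConsistency:
            suf = None
        results.append(
            ScreenResult(
                condition=cond.name,
                letter=cond.letter,
                necessity_consistency=nec,
                sufficiency_consistency=suf,
                n_with_condition=ct.n11 + ct.n10,
                n_with_condition_and_outcome=ct.n11,
                necessary_flag=thresholds.passes(nec, thresholds.necessity_cut),
                sufficient_flag=(
                    suf is not None
                    and thresholds.passes(suf, thresholds.sufficiency_cut)
                ),
            )
        )
    return results


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Screen results as a table mirroring the published layout: counts, then
    rounded necessity/sufficiency percentages, then flags."""
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "letter": r.letter,
                "n_with_condition": r.n_with_condition,
                "n_with_condition_and_outcome": r.n_with_condition_and_outcome,
                "necessity_pct": pct(r.necessity_consistency),
                "sufficiency_pct": (
                    "NA" if r.sufficiency_consistency is None
                    else pct(r.sufficiency_consistency)
                ),
                "necessary": r.necessary_flag,
                "sufficient": r.sufficient_flag,
            }
            for r in results
        ]
    )
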