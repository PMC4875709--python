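"""Truth-table construction and row classification.

The truth table enumerates all 2^k logically possible configurations of the
k condition memberships.  Each observed case is assigned to the single row
matching its bit vector; a row's consistency is the share of its cases in
the outcome set.  Rows are classified as

- ``remainder``     — fewer than ``row_n_cut`` empirical cases (a logical
                      remainder, available as a don't-care downstream),
- ``positive``      — consistency at or above ``row_incl_cut`` (outcome 1),
- ``negative``      — consistency exactly 0,
- ``contradictory`` — consistency strictly between 0 and the cut.

Only positive rows receive outcome value 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from ._rounding import round_half_up
from .dataset import CaseRecord, Dataset, ValidationError
from .screening import Thresholds

__all__ = [
    "Configuration",
    "TruthTableRow",
    "TruthTable",
    "build_truth_table",
    "summarize",
    "negate_outcome",
    "truth_table_frame",
    "MAX_CONDITIONS",
]

Configuration = tuple[int, ...]

#: Guard against exponential blowup when enumerating 2^k rows.
MAX_CONDITIONS = 20


@dataclass(frozen=True)
class TruthTableRow:
    config: Configuration
    case_ids: tuple[str, ...]
    n: int
    consistency: float | None  # defined iff n >= 1
    outcome_value: int
    status: str  # positive | negative | contradictory | remainder


@dataclass(frozen=True)
class TruthTable:
    rows: tuple[TruthTableRow, ...]
    thresholds: Thresholds
    k: int
    condition_names: tuple[str, ...]

    @property
    def positive_configs(self) -> tuple[Configuration, ...]:
        return tuple(r.config for r in self.rows if r.status == "positive")

    @property
    def negative_configs(self) -> tuple[Configuration, ...]:
        return tuple(r.config for r in self.rows if r.status == "negative")

    @property
    def contradictory_configs(self) -> tuple[Configuration, ...]:
        return tuple(r.config for r in self.rows if r.status == "contradictory")

    @property
    def remainder_configs(self) -> tuple[Configuration, ...]:
        return tuple(r.config for r in self.rows if r.status == "remainder")


def _config_index(config: Configuration) -> int:
    # leftmost condition (registry order) is the most significant bit
    idx = 0
    for bit in config:
        idx = (idx << 1) | bit
    return idx


def _index_config(idx: int, k: int) -> Configuration:
    return tuple((idx >> (k - 1 - i)) & 1 for i in range(k))


def build_truth_table(
    dataset: Dataset, thresholds: Thresholds | None = None
) -> TruthTable:
    """Enumerate all 2^k rows, assign cases by exact bit match, classify."""
    thresholds = thresholds or Thresholds()
    k = dataset.k
    if k > MAX_CONDITIONS:
        raise ValidationError(
            f"{k} conditions would require {2 ** k} truth-table rows; "
            f"the limit is {MAX_CONDITIONS} conditions"
        )

    assigned: dict[int, list[CaseRecord]] = {}
    for case in dataset.cases:
        assigned.setdefault(_config_index(dataset.configuration(case)), []).append(case)

    rows: list[TruthTableRow] = []
    for idx in range(2 ** k):
        cases = assigned.get(idx, [])
        n = len(cases)
        if n < thresholds.row_n_cut:
            consistency = (sum(c.outcome for c in cases) / n) if n else None
            status = "remainder"
        else:
            consistency = sum(c.outcome for c in cases) / n
            if thresholds.passes(consistency, thresholds.row_incl_cut):
                status = "positive"
            elif consistency == 0.0:
                status = "negative"
            else:
                status = "contradictory"
        rows.append(
            TruthTableRow(
                config=_index_config(idx, k),
                case_ids=tuple(c.case_id for c in cases),
                n=n,
                consistency=consistency,
                outcome_value=1 if status == "positive" else 0,
                status=status,
            )
        )
    return TruthTable(tuple(rows), thresholds, k, dataset.condition_names)


def summarize(tt: TruthTable) -> dict:
    """Row-status tallies plus the observed fraction of the 2^k configuration
    space (one decimal, as the limited-diversity diagnostic is reported)."""
    counts = {"positive": 0, "negative": 0, "contradictory": 0, "remainder": 0}
    for row in tt.rows:
        counts[row.status] += 1
    n_rows = len(tt.rows)
    observed = n_rows - counts["remainder"]
    return {
        "k": tt.k,
        "n_rows": n_rows,
        "observed_rows": observed,
        "remainder_rows": counts["remainder"],
        "positive_rows": counts["positive"],
        "negative_rows": counts["negative"],
        "contradictory_rows": counts["contradictory"],
        "observed_pct": round_half_up(100.0 * observed / n_rows, 1),
        "n_cases": sum(r.n for r in tt.rows),
    }


def negate_outcome(dataset: Dataset) -> Dataset:
    """Flip every case's outcome membership; conditions untouched.  Used for
    the analysis of configurations among ineffective studies."""
    cases = tuple(replace(c, outcome=1 - c.outcome) for c in dataset.cases)
    return Dataset(dataset.conditions, cases)


def truth_table_frame(tt: TruthTable) -> pd.DataFrame:
    """Truth table as a DataFrame (one row per configuration), exportable
    to CSV."""
    return pd.DataFrame(
        [
            {
                **{name: bit for name, bit in zip(tt.condition_names, row.config)},
                "n": row.n,
                "consistency": row.consistency,
                "status": row.status,
                "outcome_value": row.outcome_value,
                "case_ids": ";".join(row.case_ids),
            }
            for row in tt.rows
        ]
    )
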