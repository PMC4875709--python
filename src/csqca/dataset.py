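"""Case-by-condition data: condition registry, calibration, CSV I/O.

A *case* is one primary study; each of its conditions is a crisp set
membership (0 = fully out, 1 = fully in) recording whether the study's
intervention used a given behavior change technique (BCT).  The outcome
membership records whether the study demonstrated improved medication
adherence on at least one measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import IO, Mapping, Sequence

import pandas as pd

__all__ = [
    "ConditionDef",
    "CaseRecord",
    "Dataset",
    "CalibrationConfig",
    "ValidationError",
    "DEFAULT_REGISTRY",
    "RAW_CODES",
    "calibrate_condition",
    "calibrate_outcome",
    "read_cases",
    "write_cases",
    "registry_from_json",
]


class ValidationError(ValueError):
    """Raised when input data violate the crisp-set data contract."""


RAW_CODES = ("used", "not_used", "unclear")

_EXPECTATIONS = ("present", "absent", "none")


@dataclass(frozen=True)
class ConditionDef:
    """One condition set: a named BCT with a single-letter display label.

    ``expectation`` is the directional expectation used when deriving the
    intermediate solution: ``present`` means the condition's presence is
    expected to contribute to the outcome, ``absent`` the reverse, and
    ``none`` leaves both counterfactual directions unconstrained.
    """

    name: str
    letter: str
    expectation: str = "none"

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isalpha():
            raise ValidationError(
                f"condition {self.name!r}: letter must be a single alphabetic "
                f"character, got {self.letter!r}"
            )
        if self.expectation not in _EXPECTATIONS:
            raise ValidationError(
                f"condition {self.name!r}: expectation must be one of "
                f"{_EXPECTATIONS}, got {self.expectation!r}"
            )


#: The nine-BCT registry of the adherence analysis, in display order.
#: Directional expectations default to ``present`` for every BCT: each
#: technique is expected, when used, to contribute to improved adherence.
DEFAULT_REGISTRY: tuple[ConditionDef, ...] = (
    ConditionDef("knowledge", "K", "present"),
    ConditionDef("awareness", "R", "present"),
    ConditionDef("attitude", "T", "present"),
    ConditionDef("self_efficacy", "S", "present"),
    ConditionDef("intention_formation", "I", "present"),
    ConditionDef("action_control", "C", "present"),
    ConditionDef("maintenance", "M", "present"),
    ConditionDef("facilitation", "F", "present"),
    ConditionDef("motivational_interviewing", "G", "present"),
)


def _check_registry(conditions: Sequence[ConditionDef]) -> None:
    if len(conditions) < 1:
        raise ValidationError("registry must contain at least one condition")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValidationError("condition names must be unique")
    letters = [c.letter.lower() for c in conditions]
    if len(set(letters)) != len(letters):
        raise ValidationError(
            "condition letters must be unique (case-insensitively)"
        )


@dataclass(frozen=True)
class CaseRecord:
    """One study's crisp memberships in every condition set and the outcome."""

    case_id: str
    memberships: Mapping[str, int]
    outcome: int


@dataclass(frozen=True)
class CalibrationConfig:
    """How raw abstraction codes map to crisp memberships.

    ``unclear_mode='absent'`` (the primary analysis) codes a BCT as not used
    when the abstractors marked it unclear; ``'present'`` is the sensitivity
    analysis that assumes unclear components were present.
    """

    unclear_mode: str = "absent"

    def __post_init__(self) -> None:
        if self.unclear_mode not in ("absent", "present"):
            raise ValidationError(
                f"unclear_mode must be 'absent' or 'present', "
                f"got {self.unclear_mode!r}"
            )


def calibrate_condition(code: str, config: CalibrationConfig | None = None) -> int:
    """Map a raw condition code (used / not_used / unclear) to {0, 1}.

    ``used`` is always 1 and ``not_used`` always 0; ``unclear`` follows
    ``config.unclear_mode``.
    """
    config = config or CalibrationConfig()
    if code not in RAW_CODES:
        raise ValidationError(f"unknown raw code {code!r}; expected one of {RAW_CODES}")
    if code == "used":
        return 1
    if code == "not_used":
        return 0
    return 1 if config.unclear_mode == "present" else 0


def calibrate_outcome(improved_on_any_measure: bool) -> int:
    """Outcome set membership: 1 iff the study improved adherence on any measure."""
    return 1 if improved_on_any_measure else 0


@dataclass(frozen=True)
class Dataset:
    """An ordered condition registry plus one CaseRecord per study."""

    conditions: tuple[ConditionDef, ...]
    cases: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "cases", tuple(self.cases))
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        _check_registry(self.conditions)
        if len(self.cases) < 1:
            raise ValidationError("dataset must contain at least one case")
        seen: set[str] = set()
        names = self.condition_names
        for case in self.cases:
            if case.case_id in seen:
                raise ValidationError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)
            if set(case.memberships) != set(names):
                missing = set(names) - set(case.memberships)
                extra = set(case.memberships) - set(names)
                raise ValidationError(
                    f"case {case.case_id!r}: memberships must cover the registry "
                    f"exactly (missing {sorted(missing)}, extra {sorted(extra)})"
                )
            for name in names:
                v = case.memberships[name]
                if v not in (0, 1):
                    raise ValidationError(
                        f"case {case.case_id!r}, condition {name!r}: membership "
                        f"must be 0 or 1, got {v!r}"
                    )
            if case.outcome not in (0, 1):
                raise ValidationError(
                    f"case {case.case_id!r}: outcome must be 0 or 1, "
                    f"got {case.outcome!r}"
                )

    # -- convenience ------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.conditions)

    @property
    def n(self) -> int:
        return len(self.cases)

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    @property
    def n_outcome(self) -> int:
        """Size of the outcome set (cases with outcome membership 1)."""
        return sum(c.outcome for c in self.cases)

    def configuration(self, case: CaseRecord) -> tuple[int, ...]:
        """The case's condition bit vector in registry order."""
        return tuple(case.memberships[name] for name in self.condition_names)

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view: case_id, conditions in registry order, outcome."""
        rows = [
            {"case_id": c.case_id, **{n: c.memberships[n] for n in self.condition_names},
             "outcome": c.outcome}
            for c in self.cases
        ]
        return pd.DataFrame(rows, columns=["case_id", *self.condition_names, "outcome"])

    def with_outcomes(self, outcomes: Sequence[int]) -> "Dataset":
        if len(outcomes) != self.n:
            raise ValidationError("outcomes length must equal number of cases")
        cases = tuple(
            replace(case, outcome=int(v)) for case, v in zip(self.cases, outcomes)
        )
        return Dataset(self.conditions, cases)


_CONDITION_VOCAB = {
    "1": 1, "used": 1,
    "0": 0, "not_used": 0, "not used": 0,
    "unclear": None,  # resolved by CalibrationConfig
}
_OUTCOME_VOCAB = {"1": 1, "0": 0}


def read_cases(
    source: str | IO[str],
    registry: Sequence[ConditionDef] = DEFAULT_REGISTRY,
    config: CalibrationConfig | None = None,
) -> Dataset:
    """Read and calibrate a case table from CSV.

    The CSV must have a header with ``case_id``, one column per registry
    condition (values 0/1/unclear or used/not_used/unclear, case-insensitive),
    and an ``outcome`` column (0/1).  Row order is preserved.  Unclear codes
    are resolved per ``config.unclear_mode``.
    """
    config = config or CalibrationConfig()
    registry = tuple(registry)
    _check_registry(registry)
    try:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise ValidationError(f"cannot read case table: {exc}") from exc

    required = ["case_id", *(c.name for c in registry), "outcome"]
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")

    cases: list[CaseRecord] = []
    for idx, row in frame.iterrows():
        case_id = str(row["case_id"]).strip()
        memberships: dict[str, int] = {}
        for cond in registry:
            raw = str(row[cond.name]).strip().lower()
            if raw not in _CONDITION_VOCAB:
                raise ValidationError(
                    f"row {idx + 1} (case {case_id!r}), column {cond.name!r}: "
                    f"unrecognized value {row[cond.name]!r}"
                )
            value = _CONDITION_VOCAB[raw]
            if value is None:
                value = calibrate_condition("unclear", config)
            memberships[cond.name] = value
        raw_out = str(row["outcome"]).strip().lower()
        if raw_out not in _OUTCOME_VOCAB:
            raise ValidationError(
                f"row {idx + 1} (case {case_id!r}), column 'outcome': "
                f"unrecognized value {row['outcome']!r} (expected 0 or 1)"
            )
        cases.append(CaseRecord(case_id, memberships, _OUTCOME_VOCAB[raw_out]))

    return Dataset(registry, tuple(cases))


def write_cases(dataset: Dataset, sink: str | IO[str]) -> None:
    """Write the canonical CSV: case_id first, conditions in registry order,
    outcome last, all memberships as 0/1."""
    frame = dataset.to_frame()
    try:
        frame.to_csv(sink, index=False, lineterminator="\n")
    except OSError as exc:
        raise ValidationError(f"cannot write case table to {sink!r}: {exc}") from exc


def registry_from_json(source: str | IO[str]) -> tuple[tuple[ConditionDef, ...], CalibrationConfig]:
    """Load a registry + calibration config from a JSON file.

    Schema: ``{"conditions": [{"name", "letter", "expectation"}, ...],
    "unclear_mode": "absent"|"present"}``.
    """
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            payload = json.load(fh)
    else:
        payload = json.load(source)
    conditions = tuple(
        ConditionDef(
            name=entry["name"],
            letter=entry["letter"],
            expectation=entry.get("expectation", "none"),
        )
        for entry in payload["conditions"]
    )
    _check_registry(conditions)
    config = CalibrationConfig(unclear_mode=payload.get("unclear_mode", "absent"))
    return conditions, config
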