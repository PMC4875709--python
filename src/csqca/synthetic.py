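"""Synthetic case tables with known ground truth, plus deterministic
fixtures reconstructed from the published marginal counts and per-term
study lists of the adherence analysis.

The generator plants a set of sufficient recipes (implicants over the k
conditions), samples case configurations from an eligibility subset of the
2^k space (limited diversity), labels the outcome 1 exactly when a recipe
covers the configuration, and then flips outcomes independently at a given
noise rate (producing contradictory truth-table rows).  Ground truth is
returned on a separate channel and never leaks into the Dataset.

The two fixtures encode only what the published tables print:

- ``table2_fixture`` reproduces every per-condition marginal (n with the
  BCT, n with the BCT among the 34 effective studies) of the screening
  table; because the columns are filled independently, its joint structure
  (and hence its truth table and solutions) is NOT the original study's.
- ``table3_membership_fixture`` records the seven intermediate-solution
  terms' printed study lists and the eight uncovered effective studies,
  ready for fit-parameter scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CaseRecord, ConditionDef, Dataset, DEFAULT_REGISTRY, ValidationError
from .minimize import Implicant
from .truthtable import Configuration, _index_config

__all__ = [
    "PlantedRecipe",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "table2_fixture",
    "TABLE2_MARGINALS",
    "MembershipRecord",
    "table3_membership_fixture",
]


@dataclass(frozen=True)
class PlantedRecipe:
    """A sufficient configuration planted as ground truth."""

    implicant: Implicant
    label: str

    def __post_init__(self) -> None:
        if self.implicant.n_literals < 1:
            raise ValidationError(
                f"recipe {self.label!r} must fix at least one condition"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic case table.

    ``noise_rate`` is the independent probability of flipping a case's
    outcome after recipe labeling; ``diversity`` is the share of the 2^k
    configuration space eligible to appear (limited diversity).  Everything
    is reproducible from ``seed``.
    """

    k: int
    n_cases: int
    recipes: tuple[PlantedRecipe, ...]
    noise_rate: float = 0.0
    diversity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k:
            raise ValidationError("k must be >= 1")
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValidationError("noise_rate must lie in [0, 1)")
        if not 0.0 < self.diversity <= 1.0:
            raise ValidationError("diversity must lie in (0, 1]")
        for r in self.recipes:
            if len(r.implicant.pattern) != self.k:
                raise ValidationError(
                    f"recipe {r.label!r} pattern length != k={self.k}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did (separate from the Dataset)."""

    recipes: tuple[PlantedRecipe, ...]
    flipped_case_ids: tuple[str, ...]
    eligible_configs: tuple[Configuration, ...]

    def as_dict(self) -> dict:
        return {
            "recipes": [
                {"label": r.label,
                 "pattern": ["-" if v is None else v for v in r.implicant.pattern]}
                for r in self.recipes
            ],
            "flipped_case_ids": list(self.flipped_case_ids),
            "n_eligible_configs": len(self.eligible_configs),
        }


def _synthetic_registry(k: int) -> tuple[ConditionDef, ...]:
    if k > 26:
        raise ValidationError("synthetic registries support at most 26 conditions")
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:k]
    return tuple(ConditionDef(f"c{l}", l, "none") for l in letters)


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Generate a case table from the recipe; same seed, same bytes.

    Each eligible configuration is observed at least once whenever
    ``n_cases`` is at least the eligible count, so full diversity plus
    enough cases leaves no logical remainders.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = 2 ** spec.k
    n_eligible = max(1, int(round(spec.diversity * n_total)))
    eligible_idx = rng.choice(n_total, size=n_eligible, replace=False)
    eligible = [_index_config(int(i), spec.k) for i in sorted(eligible_idx)]

    # every eligible config once (shuffled), then uniform fill
    order = rng.permutation(n_eligible)
    picks = [eligible[i] for i in order[: min(spec.n_cases, n_eligible)]]
    if spec.n_cases > n_eligible:
        extra = rng.integers(0, n_eligible, size=spec.n_cases - n_eligible)
        picks.extend(eligible[int(i)] for i in extra)

    flips = rng.random(spec.n_cases) < spec.noise_rate
    registry = _synthetic_registry(spec.k)
    names = [c.name for c in registry]
    width = len(str(spec.n_cases))

    cases = []
    flipped: list[str] = []
    for j, config in enumerate(picks):
        case_id = f"case{j + 1:0{width}d}"
        outcome = int(any(r.implicant.covers(config) for r in spec.recipes))
        if flips[j]:
            outcome = 1 - outcome
            flipped.append(case_id)
        cases.append(
            CaseRecord(case_id, dict(zip(names, config)), outcome)
        )

    dataset = Dataset(registry, tuple(cases))
    truth = GroundTruth(spec.recipes, tuple(flipped), tuple(eligible))
    return dataset, truth


# ---------------------------------------------------------------------------
# Fixtures from the published tables
# ---------------------------------------------------------------------------

#: Per-condition printed marginals: (n studies with the BCT,
#: n with the BCT among the 34 effective studies).  60 studies total.
TABLE2_MARGINALS: dict[str, tuple[int, int]] = {
    "knowledge": (53, 31),
    "awareness": (29, 15),
    "attitude": (12, 10),
    "self_efficacy": (20, 18),
    "intention_formation": (14, 9),
    "action_control": (10, 5),
    "maintenance": (9, 5),
    "facilitation": (32, 16),
    "motivational_interviewing": (9, 7),
}

_N_CASES = 60
_N_EFFECTIVE = 34


def table2_fixture() -> Dataset:
    """Deterministic 60-case table reproducing every screening marginal.

    Cases S01..S34 are outcome-positive.  Independently per condition, the
    condition is set on the first m_eff positive cases and the first
    (m_total - m_eff) negative cases.  Only the per-condition margins are
    claimed; the joint structure is a construction artifact.
    """
    cases = []
    for j in range(_N_CASES):
        case_id = f"S{j + 1:02d}"
        outcome = 1 if j < _N_EFFECTIVE else 0
        memberships = {}
        for cond in DEFAULT_REGISTRY:
            m_total, m_eff = TABLE2_MARGINALS[cond.name]
            if outcome:
                memberships[cond.name] = 1 if j < m_eff else 0
            else:
                memberships[cond.name] = 1 if (j - _N_EFFECTIVE) < (m_total - m_eff) else 0
        cases.append(CaseRecord(case_id, memberships, outcome))
    return Dataset(DEFAULT_REGISTRY, tuple(cases))


@dataclass(frozen=True)
class MembershipRecord:
    """Published per-term study coverage, ready for fit-parameter scoring.

    ``covered_sets`` maps each solution term's letter notation to the studies
    it covers; ``outcome_ids`` is the full set of effective studies (covered
    or not).  All listed studies are effective, so every term's consistency
    is 1 by construction, as printed.
    """

    covered_sets: dict[str, frozenset[str]]
    outcome_ids: frozenset[str]
    uncovered_ids: frozenset[str]
    n_cases: int = _N_CASES


_TERM_STUDIES: dict[str, tuple[str, ...]] = {
    "KS": (
        "Berg 1997", "Janson 2003", "Janson 2009", "Johnson 2006a",
        "Johnson 2006b", "Katon 1995", "Katon 1999", "Katon 1996",
        "Katon 2001", "Murray 2007", "Ogedegbe 2012", "Rudd 2004",
        "Schaffer 2004", "Simon 2004", "Stacy 2009", "Wilson 2010",
        "Wu 2012",
    ),
    "fG": ("Berger 2005", "Friedman 1996", "Katon 2001", "Ogedegbe 2012"),
    "rSIT": ("Ogedegbe 2012", "Wolever 2010"),
    "kfCm": ("Fulmer 1999",),
    "fSmIT": ("Ogedegbe 2012", "Wolever 2010"),
    "KRFICm": ("Bosworth 2008", "Rich 1996"),
    "KrFT": ("Bogner 2012", "Bogner 2010", "Bogner 2008"),
}

_UNCOVERED_STUDIES: tuple[str, ...] = (
    "Bender 2010", "Hoffman 2003", "Lee 2006", "Okeke 2009",
    "Ross 2004", "Smith 2008", "Solomon 1998", "Waalen 2009",
)


def table3_membership_fixture() -> MembershipRecord:
    """The seven published intermediate-solution terms' study lists plus the
    eight uncovered effective studies (outcome set size 34)."""
    covered = {k: frozenset(v) for k, v in _TERM_STUDIES.items()}
    all_covered = frozenset().union(*covered.values())
    outcome = all_covered | frozenset(_UNCOVERED_STUDIES)
    assert len(outcome) == _N_EFFECTIVE
    return MembershipRecord(
        covered_sets=covered,
        outcome_ids=outcome,
        uncovered_ids=frozenset(_UNCOVERED_STUDIES),
    )
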