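"""Boolean minimization of sufficient truth-table rows and solution fit.

Positive truth-table rows are minimized with the Quine-McCluskey procedure:
rows are iteratively pair-merged into implicants until no merge applies,
yielding the prime implicants; an irredundant minimum-cardinality cover of
the positive rows is then selected (Petrick-style branch and bound).  Three
solution types differ only in which logical remainders may be absorbed as
don't-cares:

- complex       — no remainders (no simplifying assumptions),
- parsimonious  — all remainders,
- intermediate  — remainders filtered through directional expectations:
  starting from a parsimonious term, a literal of the corresponding complex
  term may stay dropped only if dropping it is an *easy* counterfactual
  (the literal contradicts, or is unconstrained by, the stated expectation);
  literals agreeing with an expectation are reinstated.

Fit parameters follow the standard crisp-set definitions: a term's
consistency is |covered ∩ outcome| / |covered|; raw coverage is
|covered ∩ outcome| / |outcome|; unique coverage counts outcome cases
covered by that term alone.  Solution totals are taken over the union of
the terms, and overlapping coverage is total minus unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._rounding import pct
from .dataset import ConditionDef, Dataset, ValidationError
from .truthtable import Configuration, TruthTable

__all__ = [
    "Implicant",
    "SolutionTerm",
    "Solution",
    "NoPositiveRows",
    "prime_implicants",
    "minimal_covers",
    "solution_complex",
    "solution_parsimonious",
    "solution_intermediate",
    "fit_parameters",
    "fit_from_membership",
    "format_configuration",
]

DASH = None  # eliminated position in an implicant pattern


class NoPositiveRows(ValueError):
    """Minimization requested but the truth table has no positive rows."""


@dataclass(frozen=True)
class Implicant:
    """A configuration pattern over the k conditions.

    Each position is 1 (condition present), 0 (absent) or None (eliminated
    during minimization).  An all-dash pattern covers every configuration.
    """

    pattern: tuple[int | None, ...]

    def covers(self, config: Configuration) -> bool:
        return all(p is DASH or p == b for p, b in zip(self.pattern, config))

    @property
    def literals(self) -> frozenset[tuple[int, int]]:
        """The fixed (position, value) pairs."""
        return frozenset(
            (i, v) for i, v in enumerate(self.pattern) if v is not DASH
        )

    @property
    def n_literals(self) -> int:
        return sum(1 for v in self.pattern if v is not DASH)

    def subsumes(self, other: "Implicant") -> bool:
        """True iff self's literals are a subset of other's, i.e. self covers
        every configuration other covers."""
        return self.literals <= other.literals

    def sort_key(self) -> tuple:
        # dashes sort after fixed bits so patterns order lexicographically
        return tuple(2 if v is DASH else v for v in self.pattern)


def prime_implicants(
    positive_rows: Iterable[Configuration],
    dontcare_rows: Iterable[Configuration] = (),
) -> set[Implicant]:
    """Quine-McCluskey prime implicants of positive ∪ don't-care rows,
    restricted to those covering at least one positive row.

    Returns the empty set (flagged by the caller) when there are no
    positive rows.
    """
    positives = {tuple(c) for c in positive_rows}
    dontcares = {tuple(c) for c in dontcare_rows}
    if positives & dontcares:
        raise ValidationError("positive and don't-care rows must be disjoint")
    if not positives:
        return set()

    # Two patterns merge iff they share the same dash positions and differ
    # in exactly one fixed bit; find partners by flipping each fixed bit and
    # probing the set, rather than scanning all pairs.
    current: set[tuple] = positives | dontcares
    primes: set[tuple] = set()
    while current:
        merged: set[tuple] = set()
        used: set[tuple] = set()
        for p in current:
            for i, v in enumerate(p):
                if v is DASH:
                    continue
                q = p[:i] + (1 - v,) + p[i + 1:]
                if q in current:
                    merged.add(p[:i] + (DASH,) + p[i + 1:])
                    used.add(p)
                    used.add(q)
        primes |= current - used
        current = merged

    return {
        Implicant(p) for p in primes
        if any(Implicant(p).covers(c) for c in positives)
    }


def minimal_covers(
    pis: Iterable[Implicant],
    positive_rows: Iterable[Configuration],
) -> list[tuple[Implicant, ...]]:
    """All minimum-cardinality irredundant covers of the positive rows.

    Covers are ordered by (number of terms, total literal count,
    lexicographic pattern order); the first entry is the canonical choice.
    Every returned cover covers all positive rows; minimum cardinality
    guarantees no redundant member.
    """
    pis = sorted(set(pis), key=Implicant.sort_key)
    positives = [tuple(c) for c in positive_rows]
    if not positives:
        return []

    coverers: dict[Configuration, list[int]] = {}
    for row in positives:
        who = [i for i, pi in enumerate(pis) if pi.covers(row)]
        if not who:
            raise ValidationError(
                f"positive row {row} is covered by no prime implicant"
            )
        coverers[row] = who

    # essential PIs appear in every cover
    essential = {who[0] for who in coverers.values() if len(who) == 1}
    remaining = [
        row for row in coverers
        if not any(i in essential for i in coverers[row])
    ]

    best_size = len(pis) + 1
    solutions: list[frozenset[int]] = []

    def search(chosen: frozenset[int], rows_left: list[Configuration]) -> None:
        nonlocal best_size, solutions
        if len(chosen) > best_size:
            return
        if not rows_left:
            if len(chosen) < best_size:
                best_size = len(chosen)
                solutions = [chosen]
            elif len(chosen) == best_size and chosen not in solutions:
                solutions.append(chosen)
            return
        if len(chosen) == best_size:
            return
        # branch on the hardest row (fewest untried coverers)
        row = min(rows_left, key=lambda r: len(coverers[r]))
        for i in coverers[row]:
            if i in chosen:
                continue
            nxt = chosen | {i}
            left = [
                r for r in rows_left
                if not any(j in nxt for j in coverers[r])
            ]
            search(nxt, left)

    search(frozenset(essential), remaining)

    def cover_key(sel: frozenset[int]) -> tuple:
        members = sorted(sel)
        return (
            sum(pis[i].n_literals for i in members),
            tuple(pis[i].sort_key() for i in members),
        )

    ordered = sorted(solutions, key=cover_key)
    return [tuple(pis[i] for i in sorted(sel)) for sel in ordered]


@dataclass(frozen=True)
class SolutionTerm:
    implicant: Implicant
    label: str
    covered_case_ids: tuple[str, ...]
    consistency: float
    raw_coverage: float
    unique_coverage: float
    n_covered_outcome: int
    n_unique_outcome: int


@dataclass(frozen=True)
class Solution:
    solution_type: str  # complex | parsimonious | intermediate
    terms: tuple[SolutionTerm, ...]
    solution_consistency: float
    total_coverage: float
    unique_coverage_total: float
    overlapping_coverage: float
    uncovered_outcome_case_ids: tuple[str, ...]
    n_covered: int
    n_covered_outcome: int
    n_unique_outcome: int
    n_alternative_covers: int = 0

    def as_dict(self) -> dict:
        """JSON-ready report: fractions plus rounded percents.

        The rounded overlapping percent is the difference of the rounded
        total and unique percents, matching how published solution tables
        print it; the exact fraction is overlapping_coverage.
        """
        total_pct = pct(self.total_coverage)
        unique_pct = pct(self.unique_coverage_total)
        return {
            "solution_type": self.solution_type,
            "terms": [
                {
                    "pattern": ["-" if v is DASH else v for v in t.implicant.pattern],
                    "label": t.label,
                    "consistency": t.consistency,
                    "consistency_pct": pct(t.consistency),
                    "raw_coverage": t.raw_coverage,
                    "raw_coverage_pct": pct(t.raw_coverage),
                    "unique_coverage": t.unique_coverage,
                    "unique_coverage_pct": pct(t.unique_coverage),
                    "n_covered_outcome": t.n_covered_outcome,
                    "n_unique_outcome": t.n_unique_outcome,
                    "covered_case_ids": list(t.covered_case_ids),
                }
                for t in self.terms
            ],
            "solution_consistency": self.solution_consistency,
            "solution_consistency_pct": pct(self.solution_consistency),
            "total_coverage": self.total_coverage,
            "total_coverage_pct": total_pct,
            "unique_coverage_total": self.unique_coverage_total,
            "unique_coverage_pct": unique_pct,
            "overlapping_coverage": self.overlapping_coverage,
            "overlapping_coverage_pct": total_pct - unique_pct,
            "uncovered_outcome_case_ids": list(self.uncovered_outcome_case_ids),
            "n_covered": self.n_covered,
            "n_covered_outcome": self.n_covered_outcome,
            "n_unique_outcome": self.n_unique_outcome,
            "n_alternative_covers": self.n_alternative_covers,
        }


def format_configuration(
    imp: Implicant, registry: Sequence[ConditionDef]
) -> str:
    """Letter notation: uppercase = condition present, lowercase = absent,
    omitted = eliminated.  An all-dash implicant formats as ''."""
    out = []
    for cond, v in zip(registry, imp.pattern):
        if v == 1:
            out.append(cond.letter.upper())
        elif v == 0:
            out.append(cond.letter.lower())
    return "".join(out)


def fit_from_membership(
    covered_sets: Mapping[str, frozenset[str]],
    outcome_ids: frozenset[str],
    solution_type: str = "intermediate",
    implicants: Mapping[str, Implicant] | None = None,
    n_alternative_covers: int = 0,
) -> Solution:
    """Fit parameters from explicit term -> covered-case-id sets.

    This is the computational core of :func:`fit_parameters`; it also lets
    coverage recorded directly (e.g. a published solution's per-term study
    lists) be scored without reconstructing full configurations.
    """
    if not covered_sets:
        raise NoPositiveRows("solution has no terms")
    if not outcome_ids:
        raise ValidationError("outcome set is empty; fit parameters undefined")

    n_outcome = len(outcome_ids)
    all_covered: set[str] = set()
    for ids in covered_sets.values():
        all_covered |= ids

    coverage_count: dict[str, int] = {}
    for ids in covered_sets.values():
        for cid in ids:
            coverage_count[cid] = coverage_count.get(cid, 0) + 1

    terms: list[SolutionTerm] = []
    for label, ids in covered_sets.items():
        covered_outcome = ids & outcome_ids
        unique_outcome = {
            cid for cid in covered_outcome if coverage_count[cid] == 1
        }
        if ids:
            consistency = len(covered_outcome) / len(ids)
        else:
            consistency = 0.0  # empirically empty term (possible with remainders)
        imp = (implicants or {}).get(label, Implicant((DASH,) * 0))
        terms.append(
            SolutionTerm(
                implicant=imp,
                label=label,
                covered_case_ids=tuple(sorted(ids)),
                consistency=consistency,
                raw_coverage=len(covered_outcome) / n_outcome,
                unique_coverage=len(unique_outcome) / n_outcome,
                n_covered_outcome=len(covered_outcome),
                n_unique_outcome=len(unique_outcome),
            )
        )

    covered_outcome_all = all_covered & outcome_ids
    unique_outcome_all = {
        cid for cid in covered_outcome_all if coverage_count[cid] == 1
    }
    total_cov = len(covered_outcome_all) / n_outcome
    unique_cov = len(unique_outcome_all) / n_outcome
    return Solution(
        solution_type=solution_type,
        terms=tuple(terms),
        solution_consistency=(
            len(covered_outcome_all) / len(all_covered) if all_covered else 0.0
        ),
        total_coverage=total_cov,
        unique_coverage_total=unique_cov,
        overlapping_coverage=total_cov - unique_cov,
        uncovered_outcome_case_ids=tuple(sorted(outcome_ids - all_covered)),
        n_covered=len(all_covered),
        n_covered_outcome=len(covered_outcome_all),
        n_unique_outcome=len(unique_outcome_all),
        n_alternative_covers=n_alternative_covers,
    )


def fit_parameters(
    terms: Sequence[Implicant],
    dataset: Dataset,
    solution_type: str = "intermediate",
    n_alternative_covers: int = 0,
) -> Solution:
    """Score a list of implicants against a dataset (see module docstring
    for the definitions)."""
    if not terms:
        raise NoPositiveRows("solution has no terms")
    outcome_ids = frozenset(c.case_id for c in dataset.cases if c.outcome == 1)
    covered_sets: dict[str, frozenset[str]] = {}
    implicants: dict[str, Implicant] = {}
    for imp in terms:
        label = format_configuration(imp, dataset.conditions)
        covered_sets[label] = frozenset(
            c.case_id for c in dataset.cases if imp.covers(dataset.configuration(c))
        )
        implicants[label] = imp
    return fit_from_membership(
        covered_sets,
        outcome_ids,
        solution_type=solution_type,
        implicants=implicants,
        n_alternative_covers=n_alternative_covers,
    )


def _best_cover(
    tt: TruthTable, dontcares: Sequence[Configuration]
) -> tuple[tuple[Implicant, ...], int]:
    positives = tt.positive_configs
    if not positives:
        raise NoPositiveRows(
            "no positive truth-table rows at the current thresholds"
        )
    pis = prime_implicants(positives, dontcares)
    covers = minimal_covers(pis, positives)
    return covers[0], len(covers) - 1


def solution_complex(tt: TruthTable, dataset: Dataset) -> Solution:
    """Minimization with no simplifying assumptions: remainders excluded."""
    cover, n_alt = _best_cover(tt, ())
    return fit_parameters(cover, dataset, "complex", n_alt)


def solution_parsimonious(tt: TruthTable, dataset: Dataset) -> Solution:
    """Minimization treating every logical remainder as a don't-care."""
    cover, n_alt = _best_cover(tt, tt.remainder_configs)
    return fit_parameters(cover, dataset, "parsimonious", n_alt)


def _expectation_vector(
    expectations: Mapping[str, str] | None, dataset: Dataset
) -> list[int | None]:
    exp: list[int | None] = [DASH] * dataset.k
    if expectations is None:
        # fall back to the registry's own directional expectations
        expectations = {c.name: c.expectation for c in dataset.conditions}
    unknown = set(expectations) - set(dataset.condition_names)
    if unknown:
        raise ValidationError(f"expectations for unknown condition(s): {sorted(unknown)}")
    for i, name in enumerate(dataset.condition_names):
        e = expectations.get(name, "none")
        if e == "present":
            exp[i] = 1
        elif e == "absent":
            exp[i] = 0
        elif e != "none":
            raise ValidationError(
                f"expectation for {name!r} must be present/absent/none, got {e!r}"
            )
    return exp


def solution_intermediate(
    tt: TruthTable,
    dataset: Dataset,
    expectations: Mapping[str, str] | None = None,
) -> Solution:
    """Counterfactual-filtered minimization.

    For each complex term T_c and parsimonious term T_p with T_p ⊆ T_c in
    literals, the intermediate term keeps T_p's literals plus every literal
    of T_c \\ T_p whose value matches the directional expectation (dropping
    such a literal would be a difficult counterfactual).  Terms are then
    deduplicated and absorbed.  A complex term with no literal-subset
    parsimonious partner is retained as-is, so every positive row stays
    covered.  With no expectations at all, every counterfactual is easy and
    the result equals the parsimonious solution.
    """
    complex_cover, _ = _best_cover(tt, ())
    pars_cover, n_alt = _best_cover(tt, tt.remainder_configs)
    exp = _expectation_vector(expectations, dataset)

    candidates: list[Implicant] = []
    for tc in complex_cover:
        paired = False
        for tp in pars_cover:
            if not tp.subsumes(tc):
                continue
            paired = True
            pattern = list(tp.pattern)
            for i, v in tc.literals - tp.literals:
                if exp[i] == v:  # dropping would contradict the expectation
                    pattern[i] = v
            candidates.append(Implicant(tuple(pattern)))
        if not paired:
            candidates.append(tc)

    # dedupe + absorption (drop any term subsumed by another)
    unique = sorted(set(candidates), key=Implicant.sort_key)
    kept = [
        t for t in unique
        if not any(o != t and o.subsumes(t) for o in unique)
    ]
    return fit_parameters(kept, dataset, "intermediate", n_alt)
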