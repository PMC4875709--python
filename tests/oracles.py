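"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive: exhaustive enumeration over the
3^k pattern space and the power set of prime implicants.  These routines
never call into the minimization code they check.
"""

from __future__ import annotations

from itertools import combinations, product


def all_configs(k: int):
    return list(product((0, 1), repeat=k))


def pattern_covers(pattern, config) -> bool:
    return all(p is None or p == b for p, b in zip(pattern, config))


def brute_force_prime_implicants(positives, dontcares, k):
    """All maximal patterns covering >=1 positive and nothing outside
    positives ∪ dontcares, by enumerating the entire 3^k pattern space."""
    allowed = set(positives) | set(dontcares)
    configs = all_configs(k)
    implicants = [
        pat for pat in product((0, 1, None), repeat=k)
        if all(c in allowed for c in configs if pattern_covers(pat, c))
    ]

    def literals(pat):
        return {(i, v) for i, v in enumerate(pat) if v is not None}

    primes = [
        pat for pat in implicants
        if not any(
            other != pat and literals(other) < literals(pat)
            for other in implicants
        )
    ]
    return {
        pat for pat in primes
        if any(pattern_covers(pat, c) for c in positives)
    }


def brute_force_minimal_covers(pi_patterns, positives):
    """All minimum-cardinality covers by exhaustive subset search."""
    pi_patterns = sorted(
        pi_patterns, key=lambda p: tuple(2 if v is None else v for v in p)
    )
    positives = list(positives)
    for size in range(1, len(pi_patterns) + 1):
        found = [
            subset
            for subset in combinations(pi_patterns, size)
            if all(
                any(pattern_covers(pat, row) for pat in subset)
                for row in positives
            )
        ]
        if found:
            return {frozenset(c) for c in found}
    return set()


def recount_contingency(dataset, condition):
    """Per-case loop recount of the 2x2 table."""
    n11 = n10 = n01 = n00 = 0
    for case in dataset.cases:
        x, y = case.memberships[condition], case.outcome
        n11 += x and y
        n10 += x and not y
        n01 += (not x) and y
        n00 += (not x) and (not y)
    return (n11, n10, n01, n00)


def groupby_row_counts(dataset):
    """Independent group-by of cases by configuration."""
    counts: dict[tuple, list[str]] = {}
    for case in dataset.cases:
        cfg = tuple(case.memberships[n] for n in dataset.condition_names)
        counts.setdefault(cfg, []).append(case.case_id)
    return counts
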