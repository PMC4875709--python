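import numpy as np
import pytest
from sympy import symbols
from sympy.logic import SOPform

from csqca.dataset import ConditionDef, ValidationError
from csqca.minimize import (
    Implicant,
    NoPositiveRows,
    fit_parameters,
    format_configuration,
    minimal_covers,
    prime_implicants,
    solution_complex,
    solution_intermediate,
    solution_parsimonious,
)
from csqca.screening import Thresholds
from csqca.truthtable import build_truth_table

from conftest import random_dataset, toy_dataset
from oracles import (
    all_configs,
    brute_force_minimal_covers,
    brute_force_prime_implicants,
    pattern_covers,
)


def random_table(k, seed, p_pos=0.3, p_dc=0.2):
    """Random disjoint positive/don't-care/negative row partition."""
    rng = np.random.default_rng(seed)
    positives, dontcares = set(), set()
    for cfg in all_configs(k):
        u = rng.random()
        if u < p_pos:
            positives.add(cfg)
        elif u < p_pos + p_dc:
            dontcares.add(cfg)
    return positives, dontcares


def covered_set(implicants, k):
    return {
        cfg for cfg in all_configs(k)
        if any(t.covers(cfg) for t in implicants)
    }


class TestPrimeImplicants:
    def test_two_positive_rows_merge(self):
        pis = prime_implicants([(1, 1), (1, 0)])
        assert {p.pattern for p in pis} == {(1, None)}

    def test_single_row_is_its_own_prime(self):
        pis = prime_implicants([(0, 1, 0)])
        assert {p.pattern for p in pis} == {(0, 1, 0)}

    def test_empty_positive_set_flagged(self):
        assert prime_implicants([]) == set()

    def test_overlapping_positive_and_dontcare_rejected(self):
        with pytest.raises(ValidationError):
            prime_implicants([(1, 1)], [(1, 1)])

    @pytest.mark.parametrize("seed", range(1, 51))
    def test_matches_exhaustive_enumeration(self, seed):
        k = 4
        positives, dontcares = random_table(k, seed)
        if not positives:
            return
        got = {p.pattern for p in prime_implicants(positives, dontcares)}
        want = brute_force_prime_implicants(positives, dontcares, k)
        assert got == want

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_matches_sympy_minimization_as_function(self, seed):
        """The minimum cover built from our PIs computes the same Boolean
        function as sympy's Quine-McCluskey on positives + don't-cares."""
        k = 4
        positives, dontcares = random_table(k, seed)
        if not positives:
            return
        pis = prime_implicants(positives, dontcares)
        cover = minimal_covers(pis, positives)[0]
        vs = symbols(f"x0:{k}")
        expr = SOPform(vs, [list(c) for c in positives],
                       [list(c) for c in dontcares])
        for cfg in all_configs(k):
            ours = any(t.covers(cfg) for t in cover)
            theirs = bool(expr.subs(dict(zip(vs, cfg))))
            if cfg in positives:
                assert ours and theirs
            elif cfg not in dontcares:
                assert not ours and not theirs


class TestMinimalCovers:
    def test_single_covering_pi(self):
        pis = {Implicant((1, None))}
        covers = minimal_covers(pis, [(1, 0), (1, 1)])
        assert covers == [(Implicant((1, None)),)]

    def test_uncoverable_row_is_a_logic_error(self):
        with pytest.raises(ValidationError, match="covered by no"):
            minimal_covers({Implicant((1, None))}, [(0, 0)])

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_essential_pi_in_every_cover(self, seed):
        k = 4
        positives, dontcares = random_table(k, seed)
        if not positives:
            return
        pis = sorted(prime_implicants(positives, dontcares), key=Implicant.sort_key)
        covers = minimal_covers(pis, positives)
        for row in positives:
            coverers = [p for p in pis if p.covers(row)]
            if len(coverers) == 1:
                assert all(coverers[0] in cover for cover in covers)

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_covers_match_exhaustive_subset_search(self, seed):
        k = 4
        positives, dontcares = random_table(k, seed)
        if not positives:
            return
        pis = prime_implicants(positives, dontcares)
        got = {frozenset(t.pattern for t in c)
               for c in minimal_covers(pis, positives)}
        want = brute_force_minimal_covers([p.pattern for p in pis], positives)
        assert got == want


class TestSolutions:
    @pytest.fixture
    def toy(self):
        # positives {11}, remainder {10}, negatives {01, 00}
        return toy_dataset([((1, 1), 1), ((0, 1), 0), ((0, 0), 0)], k=2)

    def test_complex_keeps_remainders_out(self, toy):
        tt = build_truth_table(toy)
        sol = solution_complex(tt, toy)
        assert [t.implicant.pattern for t in sol.terms] == [(1, 1)]

    def test_parsimonious_absorbs_remainder(self, toy):
        tt = build_truth_table(toy)
        sol = solution_parsimonious(tt, toy)
        assert [t.implicant.pattern for t in sol.terms] == [(1, None)]

    def test_intermediate_respects_difficult_counterfactual(self, toy):
        tt = build_truth_table(toy)
        sol = solution_intermediate(tt, toy, {"cB": "present"})
        assert [t.implicant.pattern for t in sol.terms] == [(1, 1)]

    def test_intermediate_without_expectations_is_parsimonious(self, toy):
        tt = build_truth_table(toy)
        inter = solution_intermediate(tt, toy, {})
        pars = solution_parsimonious(tt, toy)
        assert {t.implicant.pattern for t in inter.terms} == {
            t.implicant.pattern for t in pars.terms
        }

    def test_all_rows_positive_collapses_to_tautology(self):
        ds = toy_dataset([((0, 0), 1), ((0, 1), 1), ((1, 0), 1), ((1, 1), 1)], k=2)
        sol = solution_complex(build_truth_table(ds), ds)
        assert [t.implicant.pattern for t in sol.terms] == [(None, None)]

    def test_no_positive_rows_is_explicit(self):
        ds = toy_dataset([((1, 1), 0), ((0, 0), 0)], k=2)
        with pytest.raises(NoPositiveRows):
            solution_complex(build_truth_table(ds), ds)

    def test_no_remainders_parsimonious_equals_complex(self):
        rows = [(cfg, int(cfg[0])) for cfg in all_configs(3)]
        ds = toy_dataset(rows, k=3)
        tt = build_truth_table(ds)
        c = solution_complex(tt, ds)
        p = solution_parsimonious(tt, ds)
        assert {t.implicant.pattern for t in c.terms} == {
            t.implicant.pattern for t in p.terms
        }

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_soundness_completeness_and_nesting(self, seed):
        """No solution covers an observed negative row; every positive row is
        covered; complex ⊆ intermediate ⊆ parsimonious as Boolean functions."""
        rng = np.random.default_rng(seed + 1000)
        k = 4
        ds = random_dataset(k=k, n=40, seed=seed, p_outcome=0.5)
        tt = build_truth_table(ds)
        if not tt.positive_configs:
            return
        expectations = {
            c.name: rng.choice(["present", "absent", "none"])
            for c in ds.conditions
        }
        sols = {
            "complex": solution_complex(tt, ds),
            "parsimonious": solution_parsimonious(tt, ds),
            "intermediate": solution_intermediate(tt, ds, expectations),
        }
        for sol in sols.values():
            terms = [t.implicant for t in sol.terms]
            for neg in tt.negative_configs:
                assert not any(t.covers(neg) for t in terms)
            for pos in tt.positive_configs:
                assert any(t.covers(pos) for t in terms)
        fn = {name: covered_set([t.implicant for t in sol.terms], k)
              for name, sol in sols.items()}
        assert fn["complex"] <= fn["intermediate"] <= fn["parsimonious"]
        # each complex term is subsumed by some intermediate term
        for tc in sols["complex"].terms:
            assert any(ti.implicant.subsumes(tc.implicant)
                       for ti in sols["intermediate"].terms)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_complex_terms_never_cover_remainders(self, seed):
        ds = random_dataset(k=5, n=25, seed=seed, p_outcome=0.7)
        tt = build_truth_table(ds)
        if not tt.positive_configs:
            return
        sol = solution_complex(tt, ds)
        for rem in tt.remainder_configs:
            assert not any(t.implicant.covers(rem) for t in sol.terms)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_complex_function_inside_parsimonious_function(self, seed):
        """Every configuration a complex term covers is covered by the
        parsimonious solution (simplifying assumptions only ever widen
        coverage); term-by-term literal subsumption is NOT guaranteed when
        the two covers are chosen independently."""
        ds = random_dataset(k=4, n=30, seed=seed, p_outcome=0.6)
        tt = build_truth_table(ds)
        if not tt.positive_configs:
            return
        c = solution_complex(tt, ds)
        p = solution_parsimonious(tt, ds)
        pars_fn = covered_set([t.implicant for t in p.terms], 4)
        for tc in c.terms:
            assert all(cfg in pars_fn for cfg in all_configs(4)
                       if tc.implicant.covers(cfg))

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_idempotence_of_minimization(self, seed):
        """Re-minimizing a complex solution's own coverage reproduces it."""
        ds = random_dataset(k=4, n=35, seed=seed, p_outcome=0.6)
        tt = build_truth_table(ds)
        if not tt.positive_configs:
            return
        sol = solution_complex(tt, ds)
        covered = covered_set([t.implicant for t in sol.terms], 4)
        pis = prime_implicants(covered)
        again = minimal_covers(pis, covered)[0]
        assert {t.pattern for t in again} == {
            t.implicant.pattern for t in sol.terms
        }


class TestFitParameters:
    def test_single_term_covering_exactly_the_outcome_set(self):
        ds = toy_dataset([((1, 1), 1), ((0, 0), 0)], k=2)
        sol = fit_parameters([Implicant((1, 1))], ds)
        t = sol.terms[0]
        assert t.consistency == 1.0
        assert t.raw_coverage == sol.total_coverage == sol.unique_coverage_total == 1.0
        assert sol.overlapping_coverage == 0.0

    def test_overlap_arithmetic(self):
        # two terms sharing one outcome case
        ds = toy_dataset(
            [((1, 1), 1), ((1, 0), 1), ((0, 1), 1), ((0, 0), 0)], k=2
        )
        sol = fit_parameters([Implicant((1, None)), Implicant((None, 1))], ds)
        assert sol.n_covered_outcome == 3
        assert sol.n_unique_outcome == 2
        assert sol.overlapping_coverage == pytest.approx(
            sol.total_coverage - sol.unique_coverage_total
        )

    def test_empty_outcome_set_undefined(self):
        ds = toy_dataset([((1, 1), 0), ((0, 0), 0)], k=2)
        with pytest.raises(ValidationError):
            fit_parameters([Implicant((1, 1))], ds)

    def test_unique_bounded_by_raw(self, table3):
        from csqca.minimize import fit_from_membership

        sol = fit_from_membership(table3.covered_sets, table3.outcome_ids)
        for t in sol.terms:
            assert t.unique_coverage <= t.raw_coverage <= 1.0


class TestNotation:
    registry = (
        ConditionDef("knowledge", "K"),
        ConditionDef("awareness", "R"),
        ConditionDef("attitude", "T"),
        ConditionDef("self_efficacy", "S"),
        ConditionDef("intention_formation", "I"),
        ConditionDef("action_control", "C"),
        ConditionDef("maintenance", "M"),
        ConditionDef("facilitation", "F"),
        ConditionDef("motivational_interviewing", "G"),
    )

    def test_uppercase_lowercase_omitted(self):
        d = [None] * 9
        ks = d.copy()
        ks[0], ks[3] = 1, 1
        assert format_configuration(Implicant(tuple(ks)), self.registry) == "KS"
        krft = d.copy()
        krft[0], krft[1], krft[7], krft[2] = 1, 0, 1, 1
        assert format_configuration(Implicant(tuple(krft)), self.registry) == "KrTF"

    def test_all_dash_formats_empty(self):
        assert format_configuration(Implicant((None,) * 9), self.registry) == ""
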