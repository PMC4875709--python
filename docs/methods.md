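# Methods

## Model

Crisp-set QCA treats each primary study as a case with Boolean memberships
in k condition sets (here, nine behavior change techniques) and one outcome
set (improved medication adherence on at least one measure). The analysis
assumes calibration is meaningful (a technique was either a feature of the
intervention or not), that causality may be conjunctural (conditions work
in combinations) and equifinal (several combinations can each be
sufficient), and that set relations — not correlations — carry the
inference:

- **Necessity** of X for Y: consistency |X∩Y| / |Y|, the share of outcome
  cases exhibiting the condition.
- **Sufficiency** of X for Y: consistency |X∩Y| / |X|, the share of
  condition cases exhibiting the outcome. The two are exactly dual
  (sufficiency of X for Y equals necessity of Y for X), which the tests
  exploit as an algebraic identity.

The truth table enumerates all 2^k configurations; each case is assigned to
its exact configuration row. A row with at least `row_n_cut` cases is
*positive* when its outcome share reaches `row_incl_cut`, *negative* at
exactly zero, otherwise *contradictory*; unoccupied rows are *logical
remainders*. Only positive rows enter minimization; contradictory rows'
effective cases surface later as uncovered outcome cases.

## Minimization

Positive rows are reduced with the Quine–McCluskey procedure: patterns with
identical dash positions differing in one fixed bit merge until no merge
applies; unmerged patterns are the prime implicants (PIs), kept when they
cover at least one positive row. Merge partners are found by flipping each
fixed bit and probing a hash set, so each round is O(n·k) rather than
O(n²). An irredundant minimum-cardinality cover of the positive rows is
then selected by branch-and-bound (essential PIs first, then branching on
the row with fewest coverers). All co-optimal covers are enumerated;
the canonical cover is the first under (fewest terms, fewest total
literals, lexicographic pattern order), and the count of alternatives is
reported rather than hidden — model ambiguity is a finding, not noise.

The three solution types differ only in the don't-care set:

- **complex** — no remainders: the minimized function equals the positive
  row set exactly, so no simplifying assumption is made;
- **parsimonious** — every remainder is available as a don't-care;
- **intermediate** — for each complex term T_c and each parsimonious term
  T_p whose literals are a subset of T_c's, the intermediate term keeps
  T_p's literals plus every literal of T_c∖T_p whose value matches that
  condition's directional expectation (dropping such a literal would be a
  *difficult* counterfactual: it would assume the outcome occurs in
  remainder configurations that contradict the expectation). Literals
  contradicting or unconstrained by expectations stay dropped (*easy*
  counterfactuals). Terms are then deduplicated and absorbed — absorption
  runs last, after expectation filtering.

Two properties of this construction deserve care. First, a chosen complex
term may have no literal-subset partner among the chosen parsimonious
terms (the two minimum covers are selected independently); such a term is
retained unchanged so that every positive row stays covered. Second,
term-by-term literal subsumption between solution types is therefore *not*
guaranteed and is not asserted; what is guaranteed, and what the tests
assert, is nesting at the Boolean-function level — every configuration the
complex solution covers is covered by the intermediate solution, and every
one the intermediate covers is covered by the parsimonious. Soundness (no
term covers an observed negative row) and completeness (every positive row
covered) hold for all three types by construction.

The shipped nine-BCT registry sets the directional expectation *present*
for every technique — each BCT, when used, is expected to contribute to
improved adherence — and is overridable per condition.

## Fit parameters

With C(T) the cases a term covers and Y the outcome set: term consistency
= |C(T)∩Y| / |C(T)|; raw coverage = |C(T)∩Y| / |Y|; unique coverage counts
outcome cases covered by that term alone. Solution totals use the union of
the terms; overlapping coverage is total minus unique. Undefined ratios
(empty denominators) raise a typed error and are reported as
not-applicable, never coerced to 0 or 1.

Percentages print with round-half-up (not banker's rounding), which
reproduces every published cell. One printing convention follows the
published table rather than naive rounding: the overlapping-coverage
percent is the difference of the printed total and unique percents
(76 − 68 = 8 for 3/34 ≈ 8.8 %); the machine output keeps the exact
fraction.

## Thresholds and comparisons

Defaults: necessity cut 0.90, sufficiency cut 0.80, row inclusion cut 0.80,
row frequency cut 1 (single-case rows are retained — the application this
reproduces kept a configuration covering one study). Threshold comparisons
use ≥; a strict-mode switch (>) exists because verbal descriptions of
"above the threshold" are ambiguous. At the observed values the choice is
moot except exactly at a cut (e.g. a condition at exactly 0.90 is flagged
under ≥ and not under >).

## Letter notation

Configurations print as registry-order letter strings: uppercase = present,
lowercase = absent, omitted = eliminated. The registry order K, R, T, S, I,
C, M, F, G is fixed and defines bit significance everywhere (the published
term strings follow no single consistent letter order, so a convention had
to be chosen; fixture labels keep the printed strings verbatim as opaque
identifiers).

## Synthetic data and fixtures

The generator plants sufficient recipes (implicants), samples
configurations from an eligibility subset of the 2^k space (``diversity``
< 1 models limited diversity), labels outcomes by recipe coverage, and
flips each outcome independently with probability ``noise_rate`` —
producing contradictory rows, the empirical signature of measurement and
specification noise in this design. Ground truth (recipes, flip list,
eligible configurations) returns on a separate channel and never enters the
Dataset. Everything derives from one integer seed via numpy's default
generator; identical seeds give identical tables across platforms. When
``n_cases`` is at least the eligible-configuration count, every eligible
configuration is observed at least once, so full diversity plus zero noise
guarantees exact recovery of disjoint-support recipes by the parsimonious
solution; the recovery simulation (analysis/04) shows recovery eroding
quickly with noise — with ~3 cases per row, a single flipped outcome
already makes a row contradictory. Simulation sizes used throughout (k ≤ 5,
tens of cases, tens of seeds) were chosen as the smallest that exercise
every code path with stable averages.

The generator does **not** emulate: correlated condition usage across
studies (real BCTs co-occur by design tradition), unequal row occupancy,
case weights, or any upstream effect-size machinery behind the dichotomized
outcome. Passing recovery tests therefore demonstrate algorithmic
correctness, not robustness of csQCA on realistic evidence bases.

Two fixtures rebuild exactly what the published tables print and no more.
The screening fixture reproduces every per-condition marginal (60 studies,
34 effective) by filling each condition column independently with a prefix
rule; its joint structure — hence its truth table, row split and solutions —
is a construction artifact and is never claimed (its threshold sweep, for
instance, has a row at consistency 0.71 that the original data did not).
The solution fixture stores the seven intermediate-solution terms' printed
study lists directly (the terms' eliminated conditions make full 9-bit
configurations under-determined) and feeds fit-parameter scoring; the three
multiply-covered studies are taken from the lists at face value.

## Degenerate inputs and errors

Empty outcome set: necessity and fit parameters raise. Condition never
present: sufficiency reported not-applicable. No positive rows:
minimization raises a typed no-solution error at the library level; the
pipeline records an explicit no-solution result and continues. k > 20 is
refused (2^k row enumeration). Input CSVs are validated cell by cell with
the offending row and column named; missing outcome values are rejected,
not imputed.

## Known limitations

- The intermediate solution depends on the canonical cover choice when
  co-optimal covers exist; alternatives are counted but not expanded into
  alternative intermediate solutions.
- Only crisp sets are supported — no fuzzy memberships, PRI consistency, or
  enhanced remainder screens.
- Necessity coverage / relevance-of-necessity diagnostics are not computed.
- The cover search enumerates all minimum covers; pathological PI sets
  (large k with dense don't-cares) could be slow, though the guard at
  k ≤ 20 and typical evidence-synthesis sizes (k ≤ 10, n ≤ a few hundred)
  keep it well under a second.
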