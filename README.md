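# csqca — crisp-set QCA of behavior change techniques in adherence interventions

Systematic reviews of medication adherence interventions face severe
clinical and intervention heterogeneity: trials combine different behavior
change techniques (BCTs) in different populations, which usually blocks
meta-analysis. Crisp-set qualitative comparative analysis (csQCA) takes a
set-theoretic route instead: each study is a *case* with dichotomous
memberships in nine BCT condition sets — knowledge (K), awareness (R),
attitude (T), self-efficacy (S), intention formation (I), action control
(C), maintenance (M), facilitation (F), motivational interviewing (G) — and
in the outcome set of studies with significantly improved adherence. The
method asks which conditions, and which *configurations* of conditions, are
necessary or sufficient for the outcome.

This package implements the full pipeline for evidence syntheses of that
kind, and reproduces the worked-example arithmetic of a 60-study analysis
(34 effective studies) in which it was applied:

- **Calibration** (`csqca.dataset`): raw codes used / not_used / unclear to
  crisp memberships; unclear defaults to absent, with a present-mode
  sensitivity switch.
- **Screening** (`csqca.screening`): per-condition 2×2 tables;
  necessity consistency |X∩Y|/|Y|, sufficiency consistency |X∩Y|/|X|;
  cuts 0.90 (necessity) and 0.80 (sufficiency).
- **Truth table** (`csqca.truthtable`): all 2^k configurations (512 for the
  nine BCTs), row consistency, classification into positive / negative /
  contradictory / remainder rows.
- **Minimization** (`csqca.minimize`): Quine–McCluskey prime implicants and
  minimum irredundant covers; complex (no remainders), parsimonious (all
  remainders as don't-cares), and intermediate solutions (remainders
  filtered by directional expectations / easy counterfactuals); fit
  parameters — per-term and solution consistency, raw / unique / total /
  overlapping coverage.
- **Synthetic data** (`csqca.synthetic`): generator with planted sufficient
  recipes, outcome noise and limited diversity, plus deterministic fixtures
  rebuilt from the published screening marginals and solution-term study
  lists.
- **Pipeline + CLI** (`csqca.pipeline`, `csqca.cli`): one-call runs writing
  screen.csv / truthtable.csv / solution.json / report.txt, threshold-sweep
  and unclear-recoding sensitivity analyses; `csqca run|screen|truthtable|
  minimize|synth|sensitivity` from the shell.

## Worked example

```python
from csqca import (table2_fixture, screen_conditions, build_truth_table,
                   fit_from_membership, table3_membership_fixture)
from csqca._rounding import pct

ds = table2_fixture()                      # 60 cases, 34 outcome-positive
for r in screen_conditions(ds):            # necessity / sufficiency screen
    if r.necessary_flag or r.sufficient_flag:
        print(r.letter, pct(r.necessity_consistency),
              pct(r.sufficiency_consistency))

rec = table3_membership_fixture()          # published solution-term coverage
sol = fit_from_membership(rec.covered_sets, rec.outcome_ids)
d = sol.as_dict()
print(d["solution_consistency_pct"], d["total_coverage_pct"],
      d["unique_coverage_pct"], d["overlapping_coverage_pct"])
```

prints

```
K 91 58
T 29 83
S 53 90
100 76 68 8
```

Knowledge is the only necessary BCT (present in 91 % of effective studies);
attitude and self-efficacy are the only individually sufficient ones (83 %
and 90 % of the studies using them improved adherence). The seven-term
intermediate solution is perfectly consistent (every covered study is
effective), covers 76 % of effective studies (26 of 34), 68 % uniquely
(23), with 8 % overlap (3 studies covered by more than one term).

The numbered drivers under `analysis/` run each stage end to end and write
their tables to `results/`:

```sh
python analysis/01_screening.py          # necessity/sufficiency screen
python analysis/02_truth_table.py        # 512-row truth table + summary
python analysis/03_solution_fit.py       # solution fit parameters
python analysis/04_recovery_simulation.py  # planted-recipe recovery vs noise
python analysis/05_sensitivity.py        # threshold sweep, unclear recoding
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the algorithms,
the numerical conventions (rounding, tie-breaking, undefined consistencies)
and what the synthetic generator does and does not emulate.
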