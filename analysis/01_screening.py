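#!/usr/bin/env python
"""Individual-BCT necessity and sufficiency screening.

Rebuilds the 60-study case table from the published per-condition marginals
(34 studies effective) and crosses each of the nine behavior change
techniques with the outcome.  Finding: increasing knowledge is the only
necessary technique (necessity 91 %), and enhancing self-efficacy (90 %)
and improving attitude (83 %) are the only individually sufficient ones at
the 90 %/80 % cuts; motivational interviewing (78 %) just misses the
sufficiency cut.

Writes results/screening.csv.
"""

from pathlib import Path

from csqca.screening import screen_conditions, screen_table
from csqca.synthetic import table2_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dataset = table2_fixture()
    results = screen_conditions(dataset)
    table = screen_table(results)

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "screening.csv", index=False, lineterminator="\n")

    print(f"cases: {dataset.n} ({dataset.n_outcome} with improved adherence)")
    print(table.to_string(index=False))
    necessary = [r.letter for r in results if r.necessary_flag]
    sufficient = [r.letter for r in results if r.sufficient_flag]
    print(f"\nnecessary at 90 %: {necessary}; sufficient at 80 %: {sufficient}")
    print(f"wrote {OUT / 'screening.csv'}")


if __name__ == "__main__":
    main()
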