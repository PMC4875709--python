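"""End-to-end pipeline: calibration → screening → truth table →
minimization → fit, plus the two sensitivity analyses.

Machine outputs are written with fixed filenames (screen.csv,
truthtable.csv, solution.json, report.txt, run.log) so downstream harnesses
can rely on them; reruns with identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from . import __version__
from .dataset import (
    CalibrationConfig,
    ConditionDef,
    Dataset,
    DEFAULT_REGISTRY,
    ValidationError,
    read_cases,
)
from .minimize import (
    NoPositiveRows,
    Solution,
    solution_complex,
    solution_intermediate,
    solution_parsimonious,
)
from .screening import Thresholds, screen_conditions, screen_table
from .truthtable import (
    TruthTable,
    build_truth_table,
    negate_outcome,
    summarize,
    truth_table_frame,
)

__all__ = ["RunConfig", "RunResult", "run_analysis", "sensitivity_scan",
           "unclear_sensitivity", "render_report"]

log = logging.getLogger("csqca")

_SOLVERS = {
    "complex": lambda tt, ds, exp: solution_complex(tt, ds),
    "parsimonious": lambda tt, ds, exp: solution_parsimonious(tt, ds),
    "intermediate": solution_intermediate,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs."""

    input_path: str | None = None  # None → dataset passed directly
    registry: tuple[ConditionDef, ...] = DEFAULT_REGISTRY
    thresholds: Thresholds = field(default_factory=Thresholds)
    solution_type: str = "intermediate"  # complex|parsimonious|intermediate|all
    expectations: Mapping[str, str] | None = None
    negate: bool = False
    unclear_mode: str = "absent"
    output_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.solution_type not in (*_SOLVERS, "all"):
            raise ValidationError(
                f"solution_type must be one of {(*_SOLVERS, 'all')}, "
                f"got {self.solution_type!r}"
            )


@dataclass(frozen=True)
class RunResult:
    dataset: Dataset
    truth_table: TruthTable
    screen: pd.DataFrame
    summary: dict
    solutions: dict[str, Solution]
    output_files: tuple[str, ...] = ()


def render_report(result: RunResult) -> str:
    """Human-readable text report; every percentage is the round-half-up of
    the corresponding machine-output fraction."""
    lines = []
    s = result.summary
    lines.append("Crisp-set QCA run")
    lines.append(f"  cases: {s['n_cases']}  conditions: {s['k']}")
    lines.append(
        f"  truth table: {s['n_rows']} rows, {s['observed_rows']} observed "
        f"({s['observed_pct']} %), {s['remainder_rows']} remainders"
    )
    lines.append(
        f"  observed rows: {s['positive_rows']} positive, "
        f"{s['negative_rows']} negative, {s['contradictory_rows']} contradictory"
    )
    lines.append("")
    lines.append("Condition screening (necessity % / sufficiency %):")
    for _, row in result.screen.iterrows():
        flags = []
        if row["necessary"]:
            flags.append("necessary")
        if row["sufficient"]:
            flags.append("sufficient")
        lines.append(
            f"  {row['condition']} ({row['letter']}): "
            f"{row['necessity_pct']} % / {row['sufficiency_pct']} %"
            + (f"  [{', '.join(flags)}]" if flags else "")
        )
    for stype, sol in result.solutions.items():
        lines.append("")
        if sol is None:
            lines.append(f"{stype.capitalize()} solution: no sufficient rows")
            continue
        d = sol.as_dict()
        lines.append(f"{stype.capitalize()} solution ({len(sol.terms)} term(s)):")
        for t in d["terms"]:
            lines.append(
                f"  {t['label'] or '(unconditional)'}: consistency "
                f"{t['consistency_pct']} %, raw {t['raw_coverage_pct']} % "
                f"({t['n_covered_outcome']}), unique {t['unique_coverage_pct']} % "
                f"({t['n_unique_outcome']})"
            )
        lines.append(
            f"  solution consistency {d['solution_consistency_pct']} %; "
            f"coverage {d['total_coverage_pct']} % total "
            f"({d['n_covered_outcome']}), {d['unique_coverage_pct']} % unique "
            f"({d['n_unique_outcome']}), {d['overlapping_coverage_pct']} % overlapping"
        )
        lines.append(
            f"  uncovered outcome cases: {len(d['uncovered_outcome_case_ids'])}"
        )
    return "\n".join(lines) + "\n"


def run_analysis(
    config: RunConfig, dataset: Dataset | None = None
) -> RunResult:
    """Run the full pipeline; write artifacts if config.output_dir is set.

    Validation failures raise before anything is written (no partial
    outputs).
    """
    if dataset is None:
        if config.input_path is None:
            raise ValidationError("run_analysis needs an input path or a Dataset")
        dataset = read_cases(
            config.input_path,
            config.registry,
            CalibrationConfig(unclear_mode=config.unclear_mode),
        )
    if config.negate:
        dataset = negate_outcome(dataset)

    tt = build_truth_table(dataset, config.thresholds)
    screen = screen_table(screen_conditions(dataset, config.thresholds))
    summary = summarize(tt)

    wanted = list(_SOLVERS) if config.solution_type == "all" else [config.solution_type]
    solutions: dict[str, Solution | None] = {}
    for stype in wanted:
        try:
            solutions[stype] = _SOLVERS[stype](tt, dataset, config.expectations)
        except NoPositiveRows:
            # explicit no-solution result: no sufficient rows at these cuts
            solutions[stype] = None
            log.warning("%s solution: no positive truth-table rows", stype)

    result = RunResult(dataset, tt, screen, summary, solutions)

    files: list[str] = []
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        screen.to_csv(outdir / "screen.csv", index=False, lineterminator="\n")
        truth_table_frame(tt).to_csv(
            outdir / "truthtable.csv", index=False, lineterminator="\n"
        )
        payload = {
            "summary": summary,
            "solutions": {
                k: (v.as_dict() if v is not None else {"no_solution": True})
                for k, v in solutions.items()
            },
        }
        (outdir / "solution.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (outdir / "report.txt").write_text(render_report(result), encoding="utf-8")
        run_log = {
            "version": __version__,
            "input": config.input_path,
            "n_cases": dataset.n,
            "n_outcome": dataset.n_outcome,
            "thresholds": {
                "necessity_cut": config.thresholds.necessity_cut,
                "sufficiency_cut": config.thresholds.sufficiency_cut,
                "row_incl_cut": config.thresholds.row_incl_cut,
                "row_n_cut": config.thresholds.row_n_cut,
            },
            "solution_type": config.solution_type,
            "negate_outcome": config.negate,
            "unclear_mode": config.unclear_mode,
            "seed": config.seed,
        }
        (outdir / "run.log").write_text(
            json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        files = [
            str(outdir / f)
            for f in ("screen.csv", "truthtable.csv", "solution.json",
                      "report.txt", "run.log")
        ]
        log.info("wrote %d artifacts to %s", len(files), outdir)

    return replace(result, output_files=tuple(files))


def _solution_signature(sol: Solution | None) -> tuple | None:
    if sol is None:
        return None
    return tuple(sorted((t.implicant.pattern for t in sol.terms),
                        key=lambda p: tuple(2 if v is None else v for v in p)))


def sensitivity_scan(
    config: RunConfig,
    cuts: Sequence[float],
    dataset: Dataset | None = None,
) -> dict:
    """Re-run row classification and minimization across inclusion cuts.

    Reports per-cut positive-row sets and solution term patterns, and
    whether they are identical across all cuts (the published robustness
    check swept 0.70-0.90 and found no differences).
    """
    if not cuts:
        raise ValidationError("at least one cut is required")
    per_cut = {}
    for cut in cuts:
        cfg = replace(
            config,
            thresholds=replace(config.thresholds, row_incl_cut=cut),
            output_dir=None,
        )
        res = run_analysis(cfg, dataset=dataset)
        per_cut[cut] = {
            "positive_rows": frozenset(res.truth_table.positive_configs),
            "solutions": {
                k: _solution_signature(v) for k, v in res.solutions.items()
            },
        }
    baseline = next(iter(per_cut.values()))
    identical = all(v == baseline for v in per_cut.values())
    return {"cuts": list(cuts), "identical": identical, "per_cut": per_cut}


def unclear_sensitivity(
    raw_codes: str | IO[str] | pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Run the pipeline under both unclear calibrations and diff the outputs.

    ``raw_codes`` is a case table whose condition cells may be
    used/not_used/unclear (or 0/1/unclear).
    """
    results = {}
    for mode in ("absent", "present"):
        if isinstance(raw_codes, pd.DataFrame):
            import io as _io

            buf = _io.StringIO()
            raw_codes.to_csv(buf, index=False, lineterminator="\n")
            buf.seek(0)
            source: str | IO[str] = buf
        else:
            source = raw_codes
            if hasattr(source, "seek"):
                source.seek(0)
        ds = read_cases(source, config.registry, CalibrationConfig(unclear_mode=mode))
        cfg = replace(config, unclear_mode=mode, output_dir=None)
        results[mode] = run_analysis(cfg, dataset=ds)

    screen_equal = results["absent"].screen.equals(results["present"].screen)
    solutions_equal = {
        k: _solution_signature(results["absent"].solutions[k])
        == _solution_signature(results["present"].solutions[k])
        for k in results["absent"].solutions
    }
    condition_counts = {
        mode: {
            name: sum(c.memberships[name] for c in res.dataset.cases)
            for name in res.dataset.condition_names
        }
        for mode, res in results.items()
    }
    return {
        "screen_identical": screen_equal,
        "solutions_identical": solutions_equal,
        "condition_counts": condition_counts,
        "results": results,
    }
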