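"""Orchestration of exposure x outcome x instrument-set x method grids.

:func:`run_plan` executes an :class:`AnalysisPlan` over a collection of
harmonized sets (or raw exposure/outcome tables, harmonizing on the fly)
and returns a tidy results table -- one row per pooled estimate, plus
heterogeneity and MR-Egger-intercept rows per analysis cell.
:func:`reproduce_tables` runs the full grid on the bundled iron-status /
cancer case study and compares every deterministic cell against the
bundled reference estimates.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import datasets
from .diagnostics import cochran_q, egger_intercept_test
from .estimators import fit_method, mr_egger, ratio_estimates
from .summary_data import HarmonizedSet, InstrumentTable, ValidationError, harmonize

DEFAULT_METHODS = ("ivw-random", "ivw-fixed", "weighted-median", "mr-egger")

#: Named instrument subsets; ``None`` means "use every shared variant".
INSTRUMENT_SETS: dict[str, tuple[str, ...] | None] = {
    "primary-3snp": datasets.PRIMARY_VARIANTS,
    "all-snp": None,
}

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "instrument_set",
    "method",
    "n_variants",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "inflation",
    "or_point",
    "or_low",
    "or_high",
]


@dataclass(frozen=True)
class AnalysisPlan:
    """What to run: traits, instrument sets, methods, exclusions."""

    exposures: tuple[str, ...]
    outcomes: tuple[str, ...]
    methods: tuple[str, ...] = DEFAULT_METHODS
    instrument_sets: tuple[str, ...] = ("primary-3snp",)
    exclusions: tuple[str, ...] = ()
    seed: int | None = None
    n_boot: int = 10_000

    def __post_init__(self) -> None:
        for name in ("exposures", "outcomes", "methods", "instrument_sets"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        if not (self.exposures and self.outcomes and self.methods):
            raise ValidationError("plan requires non-empty exposures, outcomes and methods")
        if "weighted-median" in self.methods and self.seed is None:
            raise ValidationError("weighted-median in the plan requires a seed")
        for label in self.instrument_sets:
            if label not in INSTRUMENT_SETS:
                raise ValidationError(f"unknown instrument set {label!r}")


def _cell_rows(
    hset: HarmonizedSet, plan: AnalysisPlan, instrument_set: str
) -> list[dict[str, object]]:
    rows: list[dict[str, object]] = []
    base = {
        "exposure": hset.exposure_id,
        "outcome": hset.outcome_id,
        "instrument_set": instrument_set,
        "n_variants": len(hset),
    }

    def row(method: str, **extra) -> dict[str, object]:
        out = dict.fromkeys(RESULT_COLUMNS, np.nan)
        out.update(base)
        out["method"] = method
        out.update(extra)
        return out

    for method in plan.methods:
        if method == "mr-egger":
            if len(hset) < 3:
                rows.append(row("mr-egger", n_variants=len(hset), p=np.nan))
                continue
            fit = mr_egger(hset)
            est = fit.slope
            rows.append(
                row(
                    "mr-egger",
                    estimate=est.theta,
                    se=est.se,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    p=est.p,
                    inflation=est.inflation,
                    or_point=est.or_point,
                    or_low=est.or_low,
                    or_high=est.or_high,
                )
            )
            test = egger_intercept_test(fit)
            rows.append(
                row(
                    "mr-egger-intercept",
                    estimate=test.intercept,
                    se=test.se,
                    ci_low=test.ci_low,
                    ci_high=test.ci_high,
                    p=test.p,
                )
            )
            continue
        feasible = {"ivw-fixed": 1, "ivw-random": 1, "weighted-median": 3}[method]
        if len(hset) < feasible:
            rows.append(row(method, n_variants=len(hset)))
            continue
        est = fit_method(hset, method, seed=plan.seed, n_boot=plan.n_boot)
        rows.append(
            row(
                method,
                estimate=est.theta,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                p=est.p,
                inflation=est.inflation,
                or_point=est.or_point,
                or_low=est.or_low,
                or_high=est.or_high,
            )
        )

    if len(hset) >= 2:
        het = cochran_q(ratio_estimates(hset))
        rows.append(
            row(
                "heterogeneity",
                estimate=het.i2,
                ci_low=het.i2_low,
                ci_high=het.i2_high,
                p=het.p,
                se=het.q,  # Q statistic rides in the se column for het rows
            )
        )
    return rows


def _resolve_sets(
    plan: AnalysisPlan,
    exposure_tables: Mapping[str, InstrumentTable],
    outcome_tables: Mapping[str, InstrumentTable] | None,
    harmonized: Mapping[tuple[str, str], HarmonizedSet] | None,
) -> dict[tuple[str, str], HarmonizedSet]:
    sets: dict[tuple[str, str], HarmonizedSet] = {}
    for exposure in plan.exposures:
        for outcome in plan.outcomes:
            key = (exposure, outcome)
            if harmonized is not None and key in harmonized:
                sets[key] = harmonized[key]
                continue
            if exposure not in exposure_tables:
                raise ValidationError(f"unresolvable exposure trait {exposure!r}")
            if outcome_tables is None or outcome not in outcome_tables:
                raise ValidationError(f"unresolvable outcome trait {outcome!r}")
            sets[key] = harmonize(exposure_tables[exposure], outcome_tables[outcome])
    return sets


def run_plan(
    plan: AnalysisPlan,
    exposure_tables: Mapping[str, InstrumentTable] | None = None,
    outcome_tables: Mapping[str, InstrumentTable] | None = None,
    harmonized: Mapping[tuple[str, str], HarmonizedSet] | None = None,
) -> pd.DataFrame:
    """Run the full analysis grid and return a tidy results table.

    Analyses are resolved from ``harmonized`` when given, else by
    harmonizing ``exposure_tables[e]`` against ``outcome_tables[o]``.
    All referenced traits are resolved before any estimation starts.
    Per cell there is one row per method (MR-Egger contributes slope and
    intercept rows) plus a heterogeneity row; when the plan names
    exclusions, each cell is re-run without the excluded variants under
    an ``<instrument set>-excl`` label.
    """
    sets = _resolve_sets(plan, exposure_tables or {}, outcome_tables, harmonized)

    rows: list[dict[str, object]] = []
    for label in plan.instrument_sets:
        subset_ids = INSTRUMENT_SETS[label]
        for exposure in plan.exposures:
            for outcome in plan.outcomes:
                hset = sets[(exposure, outcome)]
                if subset_ids is not None:
                    keep = [v for v in hset.variant_ids if v in subset_ids]
                    if not keep:
                        raise ValidationError(
                            f"instrument set {label!r} shares no variants with "
                            f"({exposure}, {outcome})"
                        )
                    hset = hset.drop([v for v in hset.variant_ids if v not in keep])
                cell = HarmonizedSet(
                    exposure_id=hset.exposure_id,
                    outcome_id=hset.outcome_id,
                    pairs=hset.pairs,
                    instrument_set_label=label,
                )
                rows.extend(_cell_rows(cell, plan, label))
                if plan.exclusions:
                    kept = [v for v in cell.variant_ids if v not in plan.exclusions]
                    if kept and len(kept) < len(cell):
                        reduced = cell.drop(list(plan.exclusions))
                        rows.extend(_cell_rows(reduced, plan, f"{label}-excl"))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_log(plan: AnalysisPlan, frames: Mapping[str, pd.DataFrame]) -> dict[str, object]:
    """Provenance record: package version, seed, and input digests."""
    digests = {
        name: hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()
        for name, frame in frames.items()
    }
    return {"package": "ironmr", "version": __version__, "seed": plan.seed, "inputs": digests}


def save_results(results: pd.DataFrame, plan: AnalysisPlan, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False)
    log = run_log(plan, {"results": results})
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return out_dir / "mr_results.tsv"


# ---------------------------------------------------------------------------
# Case-study reproduction
# ---------------------------------------------------------------------------

#: Log-scale agreement budgets against the 2-3-significant-figure
#: references: relative with an absolute floor for rounding of values
#: near 1.  CI bounds get double budget because the over-dispersion
#: factor compounds input rounding.
POINT_TOL = (0.03, 0.015)
CI_TOL = (0.05, 0.03)

_ROW_FOR_METHOD = {
    "ivw-random": "ivw_random",
    "weighted-median": "weighted_median",
    "mr-egger": "mr_egger",
    "mr-egger-intercept": "pleiotropy_intercept",
    "heterogeneity": "heterogeneity",
}


def _log_close(computed: float, reference: float, tol: tuple[float, float]) -> tuple[float, bool]:
    dev = abs(math.log(computed) - math.log(reference))
    rel, floor = tol
    return dev, dev <= max(rel * abs(math.log(reference)), floor)


def reproduce_tables(seed: int = 20_200_219) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the case-study sensitivity tables and compare to references.

    Returns ``(results, comparison)``.  ``comparison`` has one row per
    checkable quantity (pooled ORs, deterministic CI bounds, I-squared,
    the serum-iron liver pleiotropy intercept) with the log-scale
    deviation and a ``within_tol`` flag.  Weighted-median CI bounds are
    bootstrap-based and p-value columns are reference-rounding-limited,
    so neither is flagged.
    """
    plan = AnalysisPlan(
        exposures=datasets.EXPOSURES,
        outcomes=datasets.OUTCOMES,
        methods=DEFAULT_METHODS,
        instrument_sets=("primary-3snp",),
        seed=seed,
    )
    results = run_plan(plan, harmonized=datasets.harmonized_sets())
    reference = datasets.reference_estimates()

    checks: list[dict[str, object]] = []
    for _, ref in reference.iterrows():
        method = {v: k for k, v in _ROW_FOR_METHOD.items()}.get(ref["row"])
        if method is None:
            continue
        sub = results[
            (results.exposure == ref["exposure"])
            & (results.outcome == ref["outcome"])
            & (results.method == method)
        ]
        if sub.empty:
            continue
        got = sub.iloc[0]

        def check(quantity: str, computed: float, reference_value: float, kind: str) -> None:
            if pd.isna(reference_value) or pd.isna(computed):
                return
            if kind == "log":
                dev, ok = _log_close(computed, reference_value, POINT_TOL)
            elif kind == "log-ci":
                dev, ok = _log_close(computed, reference_value, CI_TOL)
            elif kind == "abs":
                dev = abs(computed - reference_value)
                ok = dev <= 2.0
            else:  # linear, intercept scale
                dev = abs(computed - reference_value)
                ok = dev <= max(POINT_TOL[0] * abs(reference_value), POINT_TOL[1])
            checks.append(
                {
                    "exposure": ref["exposure"],
                    "outcome": ref["outcome"],
                    "row": ref["row"],
                    "quantity": quantity,
                    "computed": computed,
                    "reference": reference_value,
                    "deviation": dev,
                    "within_tol": ok,
                }
            )

        if ref["row"] in ("ivw_random", "weighted_median", "mr_egger"):
            check("or", got["or_point"], ref["value"], "log")
            if ref["row"] != "weighted_median":  # bootstrap CI is stochastic
                check("or_ci_low", got["or_low"], ref["ci_low"], "log-ci")
                check("or_ci_high", got["or_high"], ref["ci_high"], "log-ci")
        elif ref["row"] == "heterogeneity":
            check("i2", got["estimate"], ref["value"], "abs")
        elif ref["row"] == "pleiotropy_intercept":
            check("intercept", got["estimate"], ref["value"], "linear")
            check("intercept_ci_low", got["ci_low"], ref["ci_low"], "linear")
            check("intercept_ci_high", got["ci_high"], ref["ci_high"], "linear")
    return results, pd.DataFrame(checks)
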