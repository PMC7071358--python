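"""Heterogeneity and pleiotropy diagnostics, and sensitivity analyses.

Cochran's Q measures dispersion of the per-variant ratio estimates around
the fixed-effects pool; I-squared expresses the excess over its chi-square
expectation as a percentage.  The MR-Egger intercept test probes
directional pleiotropy.  Sensitivity analyses re-run an estimator per
variant (single-variant table), with each variant left out in turn, and
after an explicit exclusion list (by default rs1800562, the *HFE* variant
that dominates the iron-status instruments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .estimators import (
    EggerFit,
    MrEstimate,
    RatioEstimate,
    fit_method,
    ivw,
    mr_egger,
    ratio_estimates,
    wald_ratio,
)
from .summary_data import HarmonizedSet, ValidationError, Z_95


@dataclass(frozen=True)
class HetStats:
    """Cochran's Q with its chi-square p and the derived I-squared (%)."""

    q: float
    df: int
    p: float
    i2: float
    i2_low: float
    i2_high: float

    def __post_init__(self) -> None:
        if self.q < 0 or self.df < 1:
            raise ValidationError("invalid heterogeneity statistics")
        if not (0.0 <= self.i2_low <= self.i2 <= self.i2_high <= 100.0):
            raise ValidationError("I2 CI must bracket I2 within [0, 100]")


@dataclass(frozen=True)
class InterceptTest:
    """Labelled MR-Egger intercept test for directional pleiotropy."""

    intercept: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class SensitivityReport:
    """Per-variant, leave-one-out, and exclusion-rerun estimates.

    ``leave_one_out`` maps each excluded variant to the estimate on the
    remaining variants, or to ``None`` when the method is infeasible there
    (e.g. a weighted median on fewer than three variants).
    """

    method: str
    per_variant: tuple[RatioEstimate, ...]
    leave_one_out: Mapping[str, MrEstimate | None]
    excluded: tuple[str, ...] = ()
    excluded_rerun: MrEstimate | None = None


def cochran_q(ratios: Sequence[RatioEstimate]) -> HetStats:
    """Cochran's Q, its chi-square p-value, and I-squared with a 95% CI.

    ``Q = sum_j w_j (theta_j - theta_fixed)**2`` with ``df = L - 1``;
    ``I2 = max(0, (Q - df) / Q) * 100``.  The I-squared CI is the
    test-based interval on ``ln H`` (``H**2 = Q / df``) with the standard
    large-Q/small-Q standard-error cases, truncated to [0, 100].
    """
    ratios = list(ratios)
    if len(ratios) < 2:
        raise ValidationError("heterogeneity requires at least 2 ratio estimates")
    w = np.array([r.weight for r in ratios])
    theta = np.array([r.theta for r in ratios])
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    ln_h = 0.5 * math.log(q / df) if q > df else 0.0
    if q > df + 1:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (math.sqrt(2 * q) - math.sqrt(2 * df - 1))
    elif df > 1:
        se_ln_h = math.sqrt(0.5 / (df - 1) * (1.0 - 1.0 / (3.0 * (df - 1) ** 2)))
    else:
        se_ln_h = float("inf")

    def h_to_i2(ln_h_value: float) -> float:
        if not math.isfinite(ln_h_value):
            return 0.0 if ln_h_value < 0 else 100.0
        try:
            h2 = math.exp(2.0 * ln_h_value)
        except OverflowError:
            return 100.0
        return min(100.0, max(0.0, (h2 - 1.0) / h2 * 100.0))

    i2_low = h_to_i2(ln_h - Z_95 * se_ln_h)
    i2_high = h_to_i2(ln_h + Z_95 * se_ln_h)
    return HetStats(q=q, df=df, p=p, i2=i2, i2_low=min(i2_low, i2), i2_high=max(i2_high, i2))


def egger_intercept_test(fit: EggerFit) -> InterceptTest:
    """Two-sided normal test of a nonzero MR-Egger intercept."""
    return InterceptTest(
        intercept=fit.intercept,
        se=fit.se_intercept,
        ci_low=fit.intercept_ci_low,
        ci_high=fit.intercept_ci_high,
        p=fit.intercept_p,
    )


def single_variant_table(pairs: HarmonizedSet, order: str = "first") -> tuple[RatioEstimate, ...]:
    """Wald ratio per variant, in input order."""
    return tuple(wald_ratio(pair, order=order) for pair in pairs)


_MIN_VARIANTS = {"ivw-fixed": 1, "ivw-random": 2, "weighted-median": 3, "mr-egger": 3}


def leave_one_out(
    pairs: HarmonizedSet,
    method: str = "ivw-random",
    exclusions: Sequence[str] = ("rs1800562",),
    *,
    seed: int | None = None,
    n_boot: int = 10_000,
    wald_order: str = "first",
) -> SensitivityReport:
    """Leave-one-out and named-exclusion sensitivity analysis.

    For every variant, the estimator is re-run on the remaining variants;
    infeasible reruns (too few variants for the method) are recorded as
    ``None`` rather than raising.  ``exclusions`` names variants for an
    additional explicit-exclusion rerun; names absent from the set are
    ignored.
    """
    if method not in _MIN_VARIANTS:
        raise ValidationError(f"unknown method {method!r}")
    if len(pairs) < 2:
        raise ValidationError("leave-one-out requires at least 2 variants")

    def fit(subset: HarmonizedSet) -> MrEstimate | None:
        if len(subset) < _MIN_VARIANTS[method]:
            return None
        return fit_method(subset, method, seed=seed, n_boot=n_boot, wald_order=wald_order)

    loo = {vid: fit(pairs.drop([vid])) for vid in pairs.variant_ids}

    present = tuple(v for v in exclusions if v in pairs.variant_ids)
    rerun = None
    if present and len(present) < len(pairs):
        rerun = fit(pairs.drop(present))
    return SensitivityReport(
        method=method,
        per_variant=single_variant_table(pairs, order=wald_order),
        leave_one_out=loo,
        excluded=present,
        excluded_rerun=rerun,
    )
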