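"""Causal estimators for summary-data two-sample Mendelian randomization.

All estimators operate on the log-odds-ratio-per-SD scale: a ratio
estimate ``theta_j = gamma_j / beta_j`` divides a variant's outcome
log-odds association by its exposure association, and the pooled methods
combine the ``theta_j`` with inverse-variance weights ``w_j = se_j**-2``.

Implemented methods
-------------------
``wald_ratio``
    Per-variant ratio estimate with first-order (default) or second-order
    delta-method standard error.
``ivw``
    Inverse-variance weighted pooling; the random-effects variant uses a
    *multiplicative* over-dispersion model that inflates the fixed-effects
    SE by ``max(1, sqrt(Q / (L - 1)))`` where ``Q`` is Cochran's statistic.
``weighted_median``
    Median of the inverse-variance-weighted empirical distribution of
    ratio estimates; consistent when valid instruments carry more than
    half of the weight.  Its SE comes from a parametric bootstrap.
``mr_egger``
    Weighted regression of outcome on exposure associations with a free
    intercept; the intercept estimates directional pleiotropy, the slope
    estimates the causal effect under the InSIDE assumption.  Inference
    uses normal quantiles with residual over-dispersion floored at 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedPair, HarmonizedSet, ValidationError, Z_95

logger = logging.getLogger("ironmr")

METHODS = ("ivw-fixed", "ivw-random", "weighted-median", "mr-egger-slope")


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio: log-OR of outcome per SD of exposure."""

    variant_id: str
    theta: float
    se: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.variant_id}: ratio se must be > 0")

    @property
    def weight(self) -> float:
        return self.se**-2

    @property
    def z(self) -> float:
        return self.theta / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)

    @property
    def ci_low(self) -> float:
        return self.theta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z_95 * self.se


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal estimate on the log-OR-per-SD scale.

    ``inflation`` is the multiplicative SE scale applied on top of the
    fixed-effects (unit-dispersion) standard error; it is 1 for
    fixed-effects models and ``max(1, sqrt(Q / df))`` otherwise.
    """

    method: str
    n_variants: int
    theta: float
    se: float
    p: float
    inflation: float = 1.0
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.se <= 0:
            raise ValidationError("se must be > 0")
        if self.inflation < 1.0:
            raise ValidationError("inflation must be >= 1")
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.theta - Z_95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.theta + Z_95 * self.se)
        if not (self.ci_low < self.theta < self.ci_high):
            raise ValidationError("confidence interval must bracket the point estimate")

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger regression: slope (causal effect) plus pleiotropy intercept."""

    slope: MrEstimate
    intercept: float
    se_intercept: float
    residual_q: float

    def __post_init__(self) -> None:
        if self.se_intercept <= 0:
            raise ValidationError("se_intercept must be > 0")
        if self.residual_q < 0:
            raise ValidationError("residual_q must be >= 0")

    @property
    def intercept_ci_low(self) -> float:
        return self.intercept - Z_95 * self.se_intercept

    @property
    def intercept_ci_high(self) -> float:
        return self.intercept + Z_95 * self.se_intercept

    @property
    def intercept_p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.intercept / self.se_intercept)))


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------


def wald_ratio(pair: HarmonizedPair, order: str = "first") -> RatioEstimate:
    """Per-variant ratio estimate ``theta = gamma / beta``.

    ``order="first"`` ignores exposure-beta uncertainty
    (``se = se_gamma / |beta|``), which makes the ratio's z and p identical
    to those of the outcome association; ``order="second"`` adds the
    delta-method term ``gamma**2 * se_beta**2 / beta**4``.
    """
    if pair.beta_exposure == 0.0:
        raise ValidationError(f"{pair.variant_id}: zero exposure beta")
    beta, gamma = pair.beta_exposure, pair.beta_outcome
    theta = gamma / beta
    if order == "first":
        se = pair.se_outcome / abs(beta)
    elif order == "second":
        se = math.sqrt(
            pair.se_outcome**2 / beta**2 + gamma**2 * pair.se_exposure**2 / beta**4
        )
    else:
        raise ValidationError(f"unknown Wald-ratio order {order!r}")
    return RatioEstimate(variant_id=pair.variant_id, theta=theta, se=se)


def ratio_estimates(pairs: HarmonizedSet | Iterable[HarmonizedPair], order: str = "first") -> list[RatioEstimate]:
    return [wald_ratio(pair, order=order) for pair in pairs]


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def ivw(ratios: Sequence[RatioEstimate], effects: str = "random") -> MrEstimate:
    """Inverse-variance weighted pooled estimate.

    ``effects="random"`` applies the multiplicative over-dispersion model:
    the fixed-effects SE is scaled by ``max(1, sqrt(Q / (L - 1)))``, so the
    point estimate is unchanged and the SE never shrinks below the
    fixed-effects one.  A single ratio falls back to fixed effects with a
    warning.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValidationError("ivw requires at least one ratio estimate")
    if effects not in ("fixed", "random"):
        raise ValidationError(f"unknown effects model {effects!r}")

    w = np.array([r.weight for r in ratios])
    theta = np.array([r.theta for r in ratios])
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)

    if effects == "random" and len(ratios) == 1:
        warnings.warn("random-effects IVW with a single variant: returning fixed effects")
        effects = "fixed"

    if effects == "random":
        q = float(np.sum(w * (theta - theta_hat) ** 2))
        inflation = max(1.0, math.sqrt(q / (len(ratios) - 1)))
    else:
        inflation = 1.0
    se = inflation * se_fixed
    return MrEstimate(
        method=f"ivw-{effects}",
        n_variants=len(ratios),
        theta=theta_hat,
        se=se,
        p=_normal_p(theta_hat / se),
        inflation=inflation,
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


def weighted_median_point(thetas: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical distribution of ratio estimates.

    With order statistics ``theta_(1) <= ... <= theta_(L)``, normalized
    weights ``p_j`` and cumulative midpoints ``s_j = sum_{k<j} p_k + p_j/2``,
    the estimate interpolates linearly between the two order statistics
    whose ``s`` straddle one half (clamping to the extremes when 0.5 falls
    outside ``[s_1, s_L]``).
    """
    order = np.argsort(thetas, kind="stable")
    theta = np.asarray(thetas, dtype=float)[order]
    p = np.asarray(weights, dtype=float)[order]
    p = p / p.sum()
    s = np.cumsum(p) - 0.5 * p
    if s[0] > 0.5:
        return float(theta[0])
    if s[-1] < 0.5:
        return float(theta[-1])
    return float(np.interp(0.5, s, theta))


def weighted_median(
    ratios: Sequence[RatioEstimate],
    *,
    n_boot: int = 10_000,
    seed: int,
    ci_method: str = "normal",
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap replicate resamples ``theta_j ~ Normal(theta_j, se_j)``
    and recomputes the weighted median; the SE is the standard deviation
    of the replicates under ``seed``.  The point estimate does not depend
    on the bootstrap.  ``ci_method="quantile"`` replaces the normal CI by
    the 2.5/97.5 bootstrap percentiles (the p-value stays normal).
    """
    ratios = list(ratios)
    if len(ratios) < 3:
        raise ValidationError("weighted median requires at least 3 ratio estimates")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if ci_method not in ("normal", "quantile"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    theta = np.array([r.theta for r in ratios])
    se = np.array([r.se for r in ratios])
    w = np.array([r.weight for r in ratios])
    point = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, len(ratios)))
    replicates = np.array([weighted_median_point(row, w) for row in draws])
    se_boot = float(replicates.std(ddof=1))
    if se_boot <= 0.0:
        raise ValidationError("degenerate bootstrap: zero spread in replicates")

    ci: dict[str, float] = {}
    if ci_method == "quantile":
        lo, hi = np.percentile(replicates, [2.5, 97.5])
        ci = {"ci_low": min(float(lo), point), "ci_high": max(float(hi), point)}
    return MrEstimate(
        method="weighted-median",
        n_variants=len(ratios),
        theta=point,
        se=se_boot,
        p=_normal_p(point / se_boot),
        **ci,
    )


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def mr_egger(pairs: HarmonizedSet | Iterable[HarmonizedPair]) -> EggerFit:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Each pair is first oriented so its exposure beta is positive (flipping
    both betas where needed; the fit is invariant to the original signs).
    The outcome associations are regressed on the exposure associations
    with weights ``1 / se_gamma**2``; standard errors are the
    unit-dispersion weighted-least-squares ones scaled by
    ``max(1, sqrt(residual_q / (L - 2)))``, and intervals/p-values use
    normal quantiles.
    """
    pair_list = list(pairs)
    if len(pair_list) < 3:
        raise ValidationError("MR-Egger requires at least 3 pairs")
    beta = np.array([p.beta_exposure for p in pair_list])
    gamma = np.array([p.beta_outcome for p in pair_list])
    se_gamma = np.array([p.se_outcome for p in pair_list])
    if np.any(beta == 0.0):
        raise ValidationError("zero exposure beta in MR-Egger input")

    flip = np.sign(beta)
    beta = beta * flip
    gamma = gamma * flip

    w = se_gamma**-2.0
    sw = w.sum()
    swx = float(np.sum(w * beta))
    swxx = float(np.sum(w * beta**2))
    swy = float(np.sum(w * gamma))
    swxy = float(np.sum(w * beta * gamma))
    det = sw * swxx - swx**2
    if det <= 0.0:
        raise ValidationError("degenerate MR-Egger design (no spread in exposure betas)")

    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    residual_q = float(np.sum(w * (gamma - intercept - slope * beta) ** 2))
    inflation = max(1.0, math.sqrt(residual_q / (len(pair_list) - 2)))
    se_slope = inflation * math.sqrt(sw / det)
    se_intercept = inflation * math.sqrt(swxx / det)

    slope_estimate = MrEstimate(
        method="mr-egger-slope",
        n_variants=len(pair_list),
        theta=float(slope),
        se=se_slope,
        p=_normal_p(slope / se_slope),
        inflation=inflation,
    )
    return EggerFit(
        slope=slope_estimate,
        intercept=float(intercept),
        se_intercept=se_intercept,
        residual_q=residual_q,
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def fit_method(
    pairs: HarmonizedSet | Sequence[HarmonizedPair],
    method: str,
    *,
    seed: int | None = None,
    n_boot: int = 10_000,
    wald_order: str = "first",
) -> MrEstimate:
    """Run a pooled estimator by name on a harmonized set.

    ``method`` is one of ``ivw-fixed``, ``ivw-random``, ``weighted-median``
    or ``mr-egger`` (which returns the slope estimate; use
    :func:`mr_egger` directly for the intercept).
    """
    if method in ("ivw-fixed", "ivw-random"):
        return ivw(ratio_estimates(pairs, order=wald_order), effects=method.split("-")[1])
    if method == "weighted-median":
        if seed is None:
            raise ValidationError("weighted-median requires a seed")
        return weighted_median(ratio_estimates(pairs, order=wald_order), n_boot=n_boot, seed=seed)
    if method in ("mr-egger", "mr-egger-slope"):
        return mr_egger(pairs).slope
    raise ValidationError(f"unknown method {method!r}")
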