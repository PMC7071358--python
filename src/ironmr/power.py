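"""Analytic power for two-sample MR with a binary outcome.

The causal log-odds ratio per SD of exposure estimated from summary data
has approximate standard error ``1 / sqrt(n * R2 * K * (1 - K))``, where
``n`` is the outcome-study sample size, ``K`` its case fraction, and
``R2`` the fraction of exposure variance explained by the instruments.
Power for a two-sided test at level ``alpha`` against a hypothesized odds
ratio ``OR`` per SD is then::

    power = Phi(|ln OR| * sqrt(n * R2 * K * (1 - K)) - z_{1 - alpha/2})

This one-tail approximation is symmetric in ``OR`` versus ``1/OR`` and
reduces to ``alpha / 2`` at the null (``OR = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .summary_data import ValidationError


@dataclass(frozen=True)
class PowerSpec:
    """Design of a binary-outcome two-sample MR power calculation.

    Parameters
    ----------
    n
        Outcome-study sample size (cases plus controls).
    case_fraction
        Proportion of cases ``K`` in the outcome study, in (0, 1).
    r2
        Fraction of exposure variance explained by the instruments, in (0, 1).
    or_per_sd
        Hypothesized odds ratio per SD of the exposure.
    alpha
        Two-sided significance level (default 0.05).
    """

    n: float
    case_fraction: float
    r2: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name in ("case_fraction", "r2", "alpha"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValidationError(f"{name} must lie strictly in (0, 1), got {value}")
        if self.or_per_sd <= 0:
            raise ValidationError("or_per_sd must be > 0")


def mr_power_binary(spec: PowerSpec | None = None, **kwargs) -> float:
    """Power of a two-sample MR test for a binary outcome.

    Accepts either a :class:`PowerSpec` or its fields as keywords::

        mr_power_binary(n=367_643, case_fraction=324 / 367_643,
                        r2=0.034, or_per_sd=1.5)
    """
    if spec is None:
        spec = PowerSpec(**kwargs)
    elif kwargs:
        raise ValidationError("pass either a PowerSpec or keyword fields, not both")
    se_approx = 1.0 / math.sqrt(spec.n * spec.r2 * spec.case_fraction * (1.0 - spec.case_fraction))
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(abs(math.log(spec.or_per_sd)) / se_approx - z_crit))
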