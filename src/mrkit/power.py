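"""Analytical power for two-sample MR with a binary outcome.

The standard two-stage normal approximation (as implemented by the mRnd
calculator): with outcome sample size N, case fraction K, and instruments
jointly explaining a fraction R² of the exposure variance, the non-centrality
of the IVW test of a causal odds ratio OR per exposure SD is

    ncp = sqrt(N · R² · K · (1−K)) · |ln OR|

and power at two-sided level alpha is Phi(ncp − z_{1−alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .exceptions import DomainError


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the binary-outcome MR power calculation.

    n_outcome     : outcome-GWAS sample size.
    case_fraction : proportion of cases K in (0, 1).
    r2_sum        : total exposure variance explained by the instruments.
    alpha         : two-sided type-I error rate (default 0.05).
    or_target     : odds ratio whose detection power is sought.
    power_target  : power at which the detectable OR pair is sought.
    """

    n_outcome: float
    case_fraction: float
    r2_sum: float
    alpha: float = 0.05
    or_target: Optional[float] = None
    power_target: Optional[float] = None

    def __post_init__(self):
        if self.n_outcome <= 0:
            raise DomainError("n_outcome must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError("case_fraction must lie in (0, 1)")
        if not (0.0 < self.r2_sum < 1.0):
            raise DomainError("r2_sum must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must lie in (0, 1)")
        if self.or_target is not None and self.or_target <= 0:
            raise DomainError("or_target must be positive")
        if self.power_target is not None and not (0.0 < self.power_target < 1.0):
            raise DomainError("power_target must lie in (0, 1)")

    @property
    def _sqrt_info(self) -> float:
        k = self.case_fraction
        return math.sqrt(self.n_outcome * self.r2_sum * k * (1.0 - k))


def mr_power_binary(p: PowerParams) -> float:
    """Power to detect ``p.or_target`` at two-sided level ``p.alpha``."""
    if p.or_target is None:
        raise DomainError("or_target must be set for a power calculation")
    z_crit = stats.norm.ppf(1.0 - p.alpha / 2.0)
    ncp = p._sqrt_info * abs(math.log(p.or_target))
    return float(stats.norm.cdf(ncp - z_crit))


def detectable_or(p: PowerParams) -> tuple:
    """(or_low, or_high) detectable at ``p.power_target``; or_low·or_high = 1."""
    if p.power_target is None:
        raise DomainError("power_target must be set for a detectable-OR calculation")
    z_crit = stats.norm.ppf(1.0 - p.alpha / 2.0)
    z_pow = stats.norm.ppf(p.power_target)
    log_or = (z_crit + z_pow) / p._sqrt_info
    or_high = math.exp(log_or)
    return (1.0 / or_high, or_high)
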