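"""Functional estimator surface over :class:`~mrkit.model.MRModel`.

These wrappers mirror the classical per-method entry points (fixed- and
random-effects IVW, weighted median, MR-Egger) for callers that prefer
functions over the model object.  All of them accept either a sequence of
:class:`~mrkit.harmonize.HarmonizedPair` or an :class:`~mrkit.model.MRModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import MRModel, MRResult


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its first-order SE and IVW weight."""

    snp_id: str
    theta: float
    sigma: float

    @property
    def weight(self) -> float:
        return self.sigma ** -2


def as_model(pairs_or_model) -> MRModel:
    if isinstance(pairs_or_model, MRModel):
        return pairs_or_model
    return MRModel.from_pairs(list(pairs_or_model))


def ratio_estimates(pairs_or_model, second_order: bool = False) -> list:
    """Wald ratios theta_j = beta_y/beta_x with sigma_j = se_y/|beta_x|.

    Pairs with beta_x = 0 (undefined ratio) are excluded; their ids are on
    the model's ``excluded_ids``.
    """
    m = as_model(pairs_or_model)
    sig = m.ratio_se(second_order)
    return [
        RatioEstimate(s, float(t), float(g))
        for s, t, g in zip(m.snp_ids, m.ratios, sig)
    ]


def ivw_fixed(pairs_or_model) -> MRResult:
    """Fixed-effects IVW pooled estimate (= WLS of beta_y on beta_x through 0)."""
    return as_model(pairs_or_model).fit("ivw_fe")


def ivw_mre(pairs_or_model, truncate_scale: bool = True) -> MRResult:
    """Multiplicative random-effects IVW: same point estimate, SE inflated by
    max(1, sqrt(Q/(k−1)))."""
    return as_model(pairs_or_model).fit("ivw_mre", truncate_scale=truncate_scale)


def weighted_median(
    pairs_or_model, n_boot: int = 1000, seed: Optional[int] = None
) -> MRResult:
    """Weighted-median estimate with a seeded parametric-bootstrap SE."""
    return as_model(pairs_or_model).fit("weighted_median", n_boot=n_boot, seed=seed)


def egger(pairs_or_model, truncate_scale: bool = True) -> tuple:
    """MR-Egger regression; returns ``(slope_result, intercept_result)``.

    The intercept term is the directional-pleiotropy test.
    """
    res = as_model(pairs_or_model).fit("egger", truncate_scale=truncate_scale)
    return res, res.intercept
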