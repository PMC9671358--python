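"""Sensitivity analyses for two-sample MR.

Heterogeneity of the Wald ratios (Cochran's Q with its I² fraction), the
simulation-based residual-sum-of-squares outlier test (MR-PRESSO global and
per-SNP tests), leave-one-out re-estimation, and funnel-plot data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import as_model
from .exceptions import EstimationError
from .model import MRModel, MRResult

#: I² interval labels: 0–25 low, 25–50 moderate, 50–75 large, 75–100 extreme.
I2_INTERVALS = ((25.0, "low"), (50.0, "moderate"), (75.0, "large"),
                (100.0001, "extreme"))


def i2_label(i2: float) -> str:
    for bound, label in I2_INTERVALS:
        if i2 < bound:
            return label
    return "extreme"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q against chi²(k−1), with I² = max(0, (Q−df)/Q)·100%."""

    q: float
    df: int
    pval: float
    i2: float

    @property
    def label(self) -> str:
        return i2_label(self.i2)

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityResult":
        pval = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        return cls(float(q), int(df), pval, i2)

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval,
                "i2": self.i2, "label": self.label}


def cochran_q(pairs_or_model) -> HeterogeneityResult:
    """Q = Σ w_j (theta_j − theta_fe)² against chi² with k−1 df."""
    m = as_model(pairs_or_model)
    if m.k < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    theta = m.ratios
    w = m.weights()
    beta = np.sum(w * theta) / w.sum()
    q = float(np.sum(w * (theta - beta) ** 2))
    return HeterogeneityResult.from_q(q, m.k - 1)


@dataclass
class PressoResult:
    """MR-PRESSO global and per-SNP outlier test results.

    ``per_snp`` rows are (snp_id, rss_contribution, bonferroni-adjusted
    outlier p); ``outliers`` are the ids flagged below the significance
    threshold.  All Monte-Carlo p-values use the add-one convention and are
    therefore never zero.
    """

    rss_obs: float
    global_pval: float
    per_snp: list
    outliers: list
    n_sim: int
    seed: Optional[int]
    sig_threshold: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_snp, columns=["snp_id", "rss_contribution", "outlier_pval"]
        )
        df["is_outlier"] = df["snp_id"].isin(self.outliers)
        return df


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out WLS-through-origin slopes, vectorized over axis −1."""
    num = (w * by * bx).sum(axis=-1, keepdims=True) - w * by * bx
    den = (w * bx * bx).sum(axis=-1, keepdims=True) - w * bx * bx
    return num / den


def presso(
    pairs_or_model,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    sig_threshold: float = 0.05,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with per-SNP outlier detection.

    Each instrument's residual is taken against the leave-one-out IVW slope
    (so an outlier cannot mask itself), weighted by 1/se_y².  The null
    distribution is built by parametric simulation: beta_x* ~ N(beta_x, se_x)
    and beta_y* ~ N(theta_loo·beta_x, se_y), re-deriving the leave-one-out
    slopes within every replicate.  Per-SNP p-values are Bonferroni-adjusted
    by k and capped at 1.
    """
    m = as_model(pairs_or_model)
    k = m.k
    if k < 4:
        raise EstimationError("MR-PRESSO needs at least 4 instruments")
    if np.any(~np.isfinite(m.se_x)):
        raise EstimationError("MR-PRESSO simulation needs exposure SEs (se_x)")
    bx, by, sy, sx = m.beta_x, m.beta_y, m.se_y, m.se_x
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    theta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + np.count_nonzero(rss_sim >= rss_obs)) / (n_sim + 1.0)
    exceed = (resid_sim >= resid_obs).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_sim + 1.0)
    p_adj = np.minimum(1.0, p_raw * k)

    per_snp = [
        (sid, float(r), float(p))
        for sid, r, p in zip(m.snp_ids, resid_obs, p_adj)
    ]
    outliers = [sid for (sid, _, p) in per_snp if p < sig_threshold]
    return PressoResult(
        rss_obs=rss_obs, global_pval=float(global_pval), per_snp=per_snp,
        outliers=outliers, n_sim=n_sim, seed=seed, sig_threshold=sig_threshold,
    )


@dataclass
class LooTable:
    """Leave-one-out re-estimates, one row per excluded SNP."""

    rows: list  # dicts: excluded_snp, beta, se, pval, or, ci_low, ci_high
    full: MRResult
    flag: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def max_shift(self):
        """(snp_id, |delta beta|) of the exclusion that moves the estimate most."""
        deltas = [(r["excluded_snp"], abs(r["beta"] - self.full.beta))
                  for r in self.rows]
        return max(deltas, key=lambda t: t[1])


def leave_one_out(pairs_or_model, method: str = "ivw_fe") -> LooTable:
    """Re-estimate excluding each SNP in turn; flag influential exclusions.

    The flag is set when any exclusion changes the sign of beta or moves the
    95% CI across OR=1 relative to the full fit.
    """
    m = as_model(pairs_or_model)
    if m.k < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    full = m.fit(method)
    full_excl_1 = full.ci_low > 1.0 or full.ci_high < 1.0
    rows, flag = [], False
    mask = np.ones(m.k, dtype=bool)
    for j, sid in enumerate(m.snp_ids):
        mask[j] = False
        res = m.subset(mask.copy()).fit(method)
        mask[j] = True
        rows.append({
            "excluded_snp": sid, "beta": res.beta, "se": res.se,
            "pval": res.pval, "or": res.or_, "ci_low": res.ci_low,
            "ci_high": res.ci_high,
        })
        excl_1 = res.ci_low > 1.0 or res.ci_high < 1.0
        if np.sign(res.beta) != np.sign(full.beta) or excl_1 != full_excl_1:
            flag = True
    return LooTable(rows=rows, full=full, flag=flag)


def funnel_data(pairs_or_model) -> pd.DataFrame:
    """Funnel-plot table: per-SNP ratio and precision 1/sigma, most precise first."""
    m = as_model(pairs_or_model)
    if m.k < 1:
        raise EstimationError("funnel data needs at least 1 instrument")
    df = pd.DataFrame({
        "snp_id": m.snp_ids,
        "theta": m.ratios,
        "precision": 1.0 / m.ratio_se(),
    })
    return df.sort_values("precision", ascending=False, kind="stable").reset_index(
        drop=True
    )
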