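"""Two-sample Mendelian randomization model and results classes.

:class:`MRModel` holds harmonized per-SNP effect estimates
``(beta_x, se_x, beta_y, se_y)`` — the exposure and outcome associations of k
genetic instruments aligned to a common effect allele — and fits the pooled
causal estimators:

``ivw_fe``
    Fixed-effects inverse-variance-weighted mean of the Wald ratios
    theta_j = beta_y_j / beta_x_j with first-order weights
    w_j = beta_x_j² / se_y_j²; algebraically identical to weighted least
    squares of beta_y on beta_x through the origin.
``ivw_mre``
    Same point estimate; the SE is inflated by the multiplicative
    random-effects scale sqrt(Q/(k−1)), truncated below at 1.
``weighted_median``
    Consistent when instruments carrying at least half the weight are valid;
    SE by parametric bootstrap.
``egger``
    Weighted regression with an intercept; the intercept estimates the
    average directional pleiotropy and its test is the pleiotropy test.

For binary outcomes the pooled beta is a log odds ratio; results report
``or_ = exp(beta)`` with a 95% Wald interval.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, EstimationError
from .harmonize import HarmonizedPair

Z95 = 1.959964  # two-sided 95% normal quantile, to the precision used in reports

_METHODS = ("ivw_fe", "ivw_mre", "weighted_median", "egger")

# Method-name aliases accepted by fit()/CLI.
_ALIASES = {
    "fe_ivw": "ivw_fe", "ivw": "ivw_fe", "ivw_fixed": "ivw_fe",
    "mre_ivw": "ivw_mre", "ivw_random": "ivw_mre",
    "wm": "weighted_median", "median": "weighted_median",
    "mr_egger": "egger", "egger_slope": "egger",
}


def canonical_method(name: str) -> str:
    m = _ALIASES.get(name, name)
    if m not in _METHODS:
        raise ValueError(f"unknown MR method {name!r}; choose from {_METHODS}")
    return m


class MRResult:
    """A pooled causal estimate.

    Attributes
    ----------
    method : estimator name (``egger_intercept`` for the pleiotropy term).
    beta, se : pooled log-OR and its standard error.
    pval : two-sided p (normal reference; t(k−2) for Egger terms).
    k : number of instruments.
    extras : method-specific diagnostics (residual scale, bootstrap size, ...).
    """

    def __init__(self, method, beta, se, pval, k, extras=None):
        self.method = method
        self.beta = float(beta)
        self.se = float(se)
        self.pval = float(pval)
        self.k = int(k)
        self.extras = dict(extras or {})

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def conf_int(self):
        """(ci_low, ci_high) on the OR scale."""
        return (self.ci_low, self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "k": self.k, "beta": self.beta, "se": self.se,
            "pval": self.pval, "or": self.or_,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"MR estimate [{self.method}]  (k = {self.k} instruments)",
            f"  beta = {d['beta']:+.4f}   se = {d['se']:.4f}   p = {d['pval']:.3g}",
            f"  OR   = {d['or']:.3f}   95% CI [{d['ci_low']:.3f}, {d['ci_high']:.3f}]",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MRResult {self.method}: beta={self.beta:.4g} se={self.se:.4g} "
                f"p={self.pval:.3g} k={self.k}>")


class EggerResult(MRResult):
    """Egger slope result that also carries the intercept (pleiotropy) term."""

    def __init__(self, slope_kwargs, intercept: MRResult):
        super().__init__(**slope_kwargs)
        self.intercept = intercept

    def summary(self) -> str:
        i = self.intercept
        return (
            super().summary()
            + f"\n  intercept = {i.beta:+.4f}   se = {i.se:.4f}   p = {i.pval:.3g}"
            "   (directional-pleiotropy test)"
        )


class MRModel:
    """Two-sample MR model over harmonized instrument-level summary data.

    Parameters are arrays of equal length k.  ``se_x`` may be omitted for the
    IVW/Egger fits but is required for the weighted-median bootstrap and the
    outlier (MR-PRESSO) simulation.  Instruments with ``beta_x == 0`` have an
    undefined Wald ratio and are excluded at construction (recorded in
    ``excluded_ids``).
    """

    def __init__(
        self,
        beta_exposure: Sequence[float],
        se_exposure: Optional[Sequence[float]],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        snp_ids: Optional[Sequence[str]] = None,
    ):
        bx = np.asarray(beta_exposure, dtype=float)
        by = np.asarray(beta_outcome, dtype=float)
        sy = np.asarray(se_outcome, dtype=float)
        sx = (np.full_like(bx, np.nan) if se_exposure is None
              else np.asarray(se_exposure, dtype=float))
        ids = (np.asarray([f"snp_{i}" for i in range(bx.size)])
               if snp_ids is None else np.asarray(snp_ids, dtype=object))
        if not (bx.shape == by.shape == sy.shape == sx.shape == ids.shape):
            raise ValueError("all instrument arrays must share one length")
        if np.any(sy <= 0):
            raise ValueError("outcome standard errors must be positive")
        keep = bx != 0.0
        self.excluded_ids = list(ids[~keep])
        self.beta_x = bx[keep]
        self.se_x = sx[keep]
        self.beta_y = by[keep]
        self.se_y = sy[keep]
        self.snp_ids = list(ids[keep])

    @classmethod
    def from_pairs(cls, pairs: Sequence[HarmonizedPair]) -> "MRModel":
        """Build from harmonization output, using only non-dropped pairs."""
        kept = [p for p in pairs if p.kept]
        return cls(
            [p.beta_x for p in kept],
            [p.se_x for p in kept],
            [p.beta_y for p in kept],
            [p.se_y for p in kept],
            [p.snp_id for p in kept],
        )

    @classmethod
    def from_dataframe(
        cls, df, beta_x="beta_x", se_x="se_x", beta_y="beta_y", se_y="se_y",
        snp_id="snp_id",
    ) -> "MRModel":
        ids = df[snp_id] if snp_id in df.columns else None
        sx = df[se_x] if se_x in df.columns else None
        return cls(df[beta_x], sx, df[beta_y], df[se_y], ids)

    # ---------------------------------------------------------------- basics

    @property
    def k(self) -> int:
        return self.beta_x.size

    @property
    def ratios(self) -> np.ndarray:
        """Per-SNP Wald ratios beta_y / beta_x."""
        return self.beta_y / self.beta_x

    def ratio_se(self, second_order: bool = False) -> np.ndarray:
        """First-order (default) or second-order delta-method ratio SEs."""
        first = self.se_y / np.abs(self.beta_x)
        if not second_order:
            return first
        if np.any(~np.isfinite(self.se_x)):
            raise EstimationError("second-order ratio SE needs exposure SEs")
        return np.sqrt(
            self.se_y**2 / self.beta_x**2
            + self.beta_y**2 * self.se_x**2 / self.beta_x**4
        )

    def weights(self, second_order: bool = False) -> np.ndarray:
        return 1.0 / self.ratio_se(second_order) ** 2

    def subset(self, keep) -> "MRModel":
        """New model over a boolean mask or an iterable of SNP ids to keep."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            keep = np.isin(np.asarray(self.snp_ids, dtype=object), list(keep))
        return MRModel(
            self.beta_x[keep], self.se_x[keep], self.beta_y[keep],
            self.se_y[keep], list(np.asarray(self.snp_ids, dtype=object)[keep]),
        )

    def drop(self, snp_ids) -> "MRModel":
        drop = set(snp_ids if not isinstance(snp_ids, str) else [snp_ids])
        return self.subset([s for s in self.snp_ids if s not in drop])

    # ------------------------------------------------------------ estimators

    def fit(
        self,
        method: str = "ivw_fe",
        n_boot: int = 1000,
        seed: Optional[int] = None,
        truncate_scale: bool = True,
        second_order: bool = False,
    ) -> MRResult:
        method = canonical_method(method)
        if method == "ivw_fe":
            return self._fit_ivw(random_effects=False, second_order=second_order)
        if method == "ivw_mre":
            return self._fit_ivw(random_effects=True, truncate_scale=truncate_scale,
                                 second_order=second_order)
        if method == "weighted_median":
            return self._fit_weighted_median(n_boot=n_boot, seed=seed,
                                             second_order=second_order)
        return self._fit_egger(truncate_scale=truncate_scale)

    def fit_all(self, methods=_METHODS, n_boot: int = 1000,
                seed: Optional[int] = None) -> dict:
        """Fit several estimators; returns {canonical_name: MRResult}."""
        return {canonical_method(m): self.fit(m, n_boot=n_boot, seed=seed)
                for m in methods}

    def _fit_ivw(self, random_effects: bool, truncate_scale: bool = True,
                 second_order: bool = False) -> MRResult:
        k = self.k
        if k < 1 or (random_effects and k < 2):
            raise EstimationError(
                f"IVW needs at least {2 if random_effects else 1} instruments, got {k}"
            )
        theta = self.ratios
        w = self.weights(second_order)
        sw = w.sum()
        beta = float(np.sum(w * theta) / sw)
        se = float(1.0 / math.sqrt(sw))
        extras = {}
        method = "ivw_fe"
        if random_effects:
            q = float(np.sum(w * (theta - beta) ** 2))
            scale = math.sqrt(q / (k - 1))
            if truncate_scale:
                scale = max(1.0, scale)
            se *= scale
            extras = {"residual_scale": scale, "cochran_q": q}
            method = "ivw_mre"
        pval = 2.0 * stats.norm.sf(abs(beta) / se)
        return MRResult(method, beta, se, pval, k, extras)

    def _fit_weighted_median(self, n_boot: int, seed, second_order: bool) -> MRResult:
        if self.k < 3:
            raise EstimationError("weighted median needs at least 3 instruments")
        theta = self.ratios
        w = self.weights(second_order)
        beta = weighted_median(theta, w)
        if np.any(~np.isfinite(self.se_x)):
            raise EstimationError(
                "weighted-median bootstrap needs exposure SEs (se_x)"
            )
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx = rng.normal(self.beta_x, self.se_x)
            by = rng.normal(self.beta_y, self.se_y)
            bad = bx == 0.0
            if bad.any():  # measure-zero event; perturb to keep ratios finite
                bx[bad] = np.finfo(float).tiny
            t = by / bx
            sw = (self.se_y / np.abs(bx)) ** 2
            boots[b] = weighted_median(t, 1.0 / sw)
        se = float(np.std(boots, ddof=1))
        pval = 2.0 * stats.norm.sf(abs(beta) / se)
        return MRResult(
            "weighted_median", beta, se, pval, self.k,
            {"n_boot": n_boot, "seed": seed},
        )

    def _egger_design(self):
        """Orient instruments so beta_x >= 0 (allele-recoding identifiability)."""
        sign = np.where(self.beta_x < 0, -1.0, 1.0)
        return sign * self.beta_x, sign * self.beta_y

    def _fit_egger(self, truncate_scale: bool = True):
        k = self.k
        if k < 3:
            raise EstimationError("MR-Egger needs at least 3 instruments")
        bx, by = self._egger_design()
        if np.allclose(bx, bx[0]):
            raise CollinearityError(
                "MR-Egger is unidentified: all |beta_x| identical"
            )
        w = 1.0 / self.se_y**2
        X = np.column_stack([np.ones(k), bx])
        coefs, cov_unscaled, rss_w = _wls(X, by, w)
        df = k - 2
        s2 = rss_w / df
        scale = math.sqrt(s2)
        if truncate_scale:
            scale = max(1.0, scale)
        ses = scale * np.sqrt(np.diag(cov_unscaled))
        pvals = 2.0 * stats.t.sf(np.abs(coefs) / ses, df)
        extras = {"residual_scale": scale, "df": df}
        intercept = MRResult("egger_intercept", coefs[0], ses[0], pvals[0], k, extras)
        return EggerResult(
            dict(method="egger_slope", beta=coefs[1], se=ses[1], pval=pvals[1],
                 k=k, extras=extras),
            intercept,
        )


def weighted_median(theta, w) -> float:
    """Weighted median by cumulative-weight percentile interpolation.

    With weights normalized to sum 1 and ratios sorted ascending, item j sits
    at percentile p_j = S_j − w'_j/2 (S_j the cumulative weight); the estimate
    interpolates theta linearly across the bracketing percentiles at 0.5.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - 0.5 * wn
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    return float(np.interp(0.5, p, t))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via the scaled design; returns
    (coefs, unscaled covariance (X'WX)^-1, weighted RSS)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise CollinearityError("design matrix is singular") from None
    coefs = cov @ (Xw.T @ yw)
    resid = yw - Xw @ coefs
    return coefs, cov, float(resid @ resid)
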