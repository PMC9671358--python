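"""Multivariable Mendelian randomization (MVMR).

Regresses the outcome associations of a joint instrument set on the per-SNP
associations with several exposures simultaneously (weighted least squares
without intercept, weights 1/se_y²), giving each exposure's direct effect
conditional on the others — e.g. the effect of age at menarche on ischemic
heart disease adjusted for adult or childhood body-mass index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, EstimationError
from .harmonize import harmonize_pair
from .instruments import SelectionConfig, clump, select_significant
from .io import LDTable, SummaryDataset
from .model import MRResult, _wls


@dataclass
class MVMRInput:
    """Joint instrument-level data for E exposures and one outcome.

    ``beta_x``/``se_x`` are J×E arrays (column e = exposure e's effects over
    the J instruments, all aligned to a common effect allele); ``beta_y`` and
    ``se_y`` are length-J outcome arrays.
    """

    snp_ids: list
    exposure_labels: list
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.snp_ids) > 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, e = self.beta_x.shape
        if (len(self.snp_ids) != j or len(self.exposure_labels) != e
                or self.beta_y.shape != (j,) or self.se_y.shape != (j,)
                or self.se_x.shape != (j, e)):
            raise ValueError("inconsistent MVMR input dimensions")
        if np.any(self.se_y <= 0) or np.any(self.se_x <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def j(self) -> int:
        return self.beta_x.shape[0]

    @property
    def e(self) -> int:
        return self.beta_x.shape[1]


class MVMRModel:
    """Multivariable IVW model; ``fit()`` returns one result per exposure."""

    def __init__(self, data: MVMRInput):
        self.data = data

    def fit(self, truncate_scale: bool = True) -> list:
        d = self.data
        if d.j <= d.e:
            raise EstimationError(
                f"MVMR needs more instruments than exposures (J={d.j}, E={d.e})"
            )
        X = d.beta_x
        if np.linalg.matrix_rank(X) < d.e:
            offenders = _collinear_columns(X, d.exposure_labels)
            raise CollinearityError(
                "MVMR design is rank deficient; collinear exposures: "
                + ", ".join(offenders), exposures=offenders,
            )
        w = 1.0 / d.se_y**2
        coefs, cov_unscaled, rss_w = _wls(X, d.beta_y, w)
        df = d.j - d.e
        scale = np.sqrt(rss_w / df)
        if truncate_scale:
            scale = max(1.0, scale)
        ses = scale * np.sqrt(np.diag(cov_unscaled))
        pvals = 2.0 * stats.t.sf(np.abs(coefs) / ses, df)
        extras = {"residual_scale": float(scale), "df": df,
                  "exposures": list(d.exposure_labels)}
        return [
            MRResult("mvmr_ivw", b, s, p, d.j, {**extras, "exposure": lab})
            for lab, b, s, p in zip(d.exposure_labels, coefs, ses, pvals)
        ]


def mvmr_ivw(data: MVMRInput, truncate_scale: bool = True) -> list:
    """Functional entry point; see :class:`MVMRModel`."""
    return MVMRModel(data).fit(truncate_scale=truncate_scale)


def _collinear_columns(X: np.ndarray, labels) -> list:
    """Name exposures involved in exact linear dependence (via correlation)."""
    e = X.shape[1]
    bad = set()
    for a in range(e):
        for b in range(a + 1, e):
            ca, cb = X[:, a], X[:, b]
            denom = np.linalg.norm(ca - ca.mean()) * np.linalg.norm(cb - cb.mean())
            if denom == 0 or abs(np.corrcoef(ca, cb)[0, 1]) > 1 - 1e-12:
                bad.update((labels[a], labels[b]))
    return sorted(bad) if bad else list(labels)


def mvmr_harmonize(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    cfg: Optional[SelectionConfig] = None,
    ambiguity_window: float = 0.08,
    ld: Optional[LDTable] = None,
) -> MVMRInput:
    """Build an :class:`MVMRInput` from raw exposure and outcome datasets.

    The joint instrument set is the union of each exposure's genome-wide
    significant SNPs, clumped jointly on the minimum p across exposures; a
    retained SNP must be present in every dataset.  All datasets are aligned
    to the first exposure's allele orientation via pairwise harmonization;
    a SNP any dataset fails to harmonize is dropped (reasons recorded on the
    returned object's ``dropped`` attribute).
    """
    if len(exposures) < 1:
        raise EstimationError("mvmr_harmonize needs at least one exposure")
    cfg = cfg or SelectionConfig()

    selected = [select_significant(ds, cfg) for ds in exposures]
    union_ids: list = []
    best: dict = {}
    for ds in selected:
        for r in ds.records:
            if r.snp_id not in best:
                union_ids.append(r.snp_id)
                best[r.snp_id] = r
            elif r.pval < best[r.snp_id].pval:
                best[r.snp_id] = r
    if not union_ids:
        raise EstimationError("no genome-wide-significant instruments in any exposure")

    # Joint clumping on the min-p representative of each SNP.
    joint = SummaryDataset(
        "joint", "continuous", [best[i] for i in union_ids], source="mvmr-union"
    )
    clumped = clump(joint, ld, cfg)
    ids = [r.snp_id for r in clumped.records]

    maps = [{r.snp_id: r for r in ds.records} for ds in exposures]
    ymap = {r.snp_id: r for r in outcome.records}

    dropped: list = []
    rows_bx, rows_sx, by, sy, kept_ids = [], [], [], [], []
    for sid in ids:
        if any(sid not in mp for mp in maps):
            dropped.append((sid, "missing_in_exposure"))
            continue
        if sid not in ymap:
            dropped.append((sid, "missing_in_outcome"))
            continue
        ref = maps[0][sid]
        bx_row, sx_row, ok = [ref.beta], [ref.se], True
        for mp in maps[1:]:
            hp = harmonize_pair(ref, mp[sid], ambiguity_window)
            if not hp.kept:
                dropped.append((sid, hp.status))
                ok = False
                break
            bx_row.append(hp.beta_y)
            sx_row.append(hp.se_y)
        if not ok:
            continue
        hy = harmonize_pair(ref, ymap[sid], ambiguity_window)
        if not hy.kept:
            dropped.append((sid, hy.status))
            continue
        rows_bx.append(bx_row)
        rows_sx.append(sx_row)
        by.append(hy.beta_y)
        sy.append(hy.se_y)
        kept_ids.append(sid)

    if not kept_ids:
        raise EstimationError("no instruments survived MVMR harmonization")
    out = MVMRInput(
        snp_ids=kept_ids,
        exposure_labels=[ds.trait_label for ds in exposures],
        beta_x=np.asarray(rows_bx), se_x=np.asarray(rows_sx),
        beta_y=np.asarray(by), se_y=np.asarray(sy),
    )
    out.dropped = dropped
    return out
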