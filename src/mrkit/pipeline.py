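"""End-to-end two-sample MR workflow.

:func:`run_study` executes the full analysis on in-memory datasets —
instrument selection, clumping, harmonization, the four causal estimators,
heterogeneity/outlier/leave-one-out sensitivity analyses, an optional
confounder-filtered re-analysis, optional multivariable MR adjustments, and
power — and returns a validated :class:`RunReport`.  :func:`run_pipeline`
wraps it with file IO for the command line.

Whenever the outlier test flags SNPs, every estimator and heterogeneity test
is re-run without them and both sets of results are reported; the same
estimate→outlier→re-estimate cycle is applied to the confounder-filtered
instrument set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import ConfigurationError, EstimationError, MRKitError
from .harmonize import harmonize_datasets
from .instruments import (
    SelectionConfig,
    clump,
    filter_confounders,
    select_significant,
    variance_explained,
)
from .io import (
    ColumnMap,
    ConfounderAssocTable,
    LDTable,
    SummaryDataset,
    read_confounder_table,
    read_ld_table,
    read_summary_table,
)
from .model import MRModel
from .power import PowerParams, detectable_or, mr_power_binary
from .mvmr import mvmr_harmonize, mvmr_ivw
from .sensitivity import cochran_q, funnel_data, leave_one_out, presso

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_fe", "ivw_mre", "weighted_median", "egger")


class StageCount(BaseModel):
    stage: str
    offered: int
    kept: int
    dropped: int
    details: Dict[str, Any] = Field(default_factory=dict)


class AnalysisBlock(BaseModel):
    """Estimates plus sensitivity results for one instrument set."""

    k: int
    estimates: Dict[str, Dict[str, Any]]
    heterogeneity: Optional[Dict[str, Any]] = None
    presso: Optional[Dict[str, Any]] = None
    loo: Optional[Dict[str, Any]] = None


class RunReport(BaseModel):
    """Consolidated, schema-validated record of one pipeline run."""

    software: str = "mrkit"
    version: str = __version__
    seed: int = 0
    config: Dict[str, Any] = Field(default_factory=dict)
    stages: List[StageCount] = Field(default_factory=list)
    harmonization: Dict[str, Any] = Field(default_factory=dict)
    primary: Optional[AnalysisBlock] = None
    post_outlier: Optional[AnalysisBlock] = None
    confounder_filtered: Optional[AnalysisBlock] = None
    confounder_filtered_post_outlier: Optional[AnalysisBlock] = None
    mvmr: List[Dict[str, Any]] = Field(default_factory=list)
    power: Dict[str, Any] = Field(default_factory=dict)
    errors: List[str] = Field(default_factory=list)

    def counts_conserved(self) -> bool:
        return all(s.offered == s.kept + s.dropped for s in self.stages)


def _mr_block(
    model: MRModel,
    methods,
    seed: int,
    n_boot: int,
    presso_sims: int,
    with_sensitivity: bool = True,
) -> AnalysisBlock:
    estimates: Dict[str, Dict[str, Any]] = {}
    for m in methods:
        res = model.fit(m, n_boot=n_boot, seed=seed)
        estimates[res.method] = res.to_dict()
        if res.method == "egger_slope" or res.method.startswith("egger"):
            estimates["egger_intercept"] = res.intercept.to_dict()
    block = AnalysisBlock(k=model.k, estimates=estimates)
    if with_sensitivity and model.k >= 2:
        block.heterogeneity = cochran_q(model).to_dict()
    if with_sensitivity and model.k >= 4:
        pr = presso(model, n_sim=presso_sims, seed=seed)
        block.presso = {
            "rss_obs": pr.rss_obs, "global_pval": pr.global_pval,
            "outliers": pr.outliers, "n_sim": pr.n_sim,
        }
    if with_sensitivity and model.k >= 3:
        loo = leave_one_out(model)
        snp, delta = loo.max_shift()
        block.loo = {"flag": loo.flag, "n_rows": len(loo.rows),
                     "max_shift_snp": snp, "max_shift_delta": delta}
    return block


def run_study(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: Optional[LDTable] = None,
    confounders: Optional[ConfounderAssocTable] = None,
    covariates: Optional[List[SummaryDataset]] = None,
    selection: Optional[SelectionConfig] = None,
    ambiguity_window: float = 0.08,
    methods=DEFAULT_METHODS,
    seed: int = 0,
    n_boot: int = 1000,
    presso_sims: int = 1000,
    power_or: float = 0.80,
    power_target: float = 0.80,
) -> RunReport:
    """Run the complete study workflow on in-memory datasets."""
    cfg = selection or SelectionConfig()
    report = RunReport(seed=seed, config={
        "selection": cfg.__dict__, "ambiguity_window": ambiguity_window,
        "methods": list(methods), "n_boot": n_boot, "presso_sims": presso_sims,
    })

    sig = select_significant(exposure, cfg)
    report.stages.append(StageCount(
        stage="select_significant", offered=len(exposure), kept=len(sig),
        dropped=len(exposure) - len(sig),
    ))
    clumped = clump(sig, ld, cfg)
    report.stages.append(StageCount(
        stage="clump", offered=len(sig), kept=len(clumped),
        dropped=len(sig) - len(clumped),
        details={"removals": getattr(clumped, "clump_removals", [])},
    ))

    pairs, hrep = harmonize_datasets(clumped, outcome, ambiguity_window)
    report.harmonization = {
        "counts": dict(hrep.counts), "dropped": hrep.dropped,
        "offered": hrep.offered, "kept": hrep.kept,
    }
    report.stages.append(StageCount(
        stage="harmonize", offered=hrep.offered, kept=hrep.kept,
        dropped=hrep.offered - hrep.kept,
    ))

    model = MRModel.from_pairs(pairs)
    try:
        report.primary = _mr_block(model, methods, seed, n_boot, presso_sims)
    except (EstimationError, MRKitError) as exc:
        report.errors.append(f"primary: {exc}")
        return report

    outliers = (report.primary.presso or {}).get("outliers", [])
    if outliers:
        try:
            report.post_outlier = _mr_block(
                model.drop(outliers), methods, seed, n_boot, presso_sims
            )
        except (EstimationError, MRKitError) as exc:
            report.errors.append(f"post_outlier: {exc}")

    if confounders is not None:
        filtered = filter_confounders(clumped, confounders, cfg.p_threshold)
        drops = getattr(filtered, "confounder_drops", {})
        report.stages.append(StageCount(
            stage="filter_confounders", offered=len(clumped), kept=len(filtered),
            dropped=len(clumped) - len(filtered),
            details={"dropped_snps": {k: v for k, v in drops.items()}},
        ))
        fpairs, _ = harmonize_datasets(filtered, outcome, ambiguity_window)
        fmodel = MRModel.from_pairs(fpairs)
        try:
            report.confounder_filtered = _mr_block(
                fmodel, methods, seed, n_boot, presso_sims
            )
            fout = (report.confounder_filtered.presso or {}).get("outliers", [])
            if fout:
                report.confounder_filtered_post_outlier = _mr_block(
                    fmodel.drop(fout), methods, seed, n_boot, presso_sims
                )
        except (EstimationError, MRKitError) as exc:
            report.errors.append(f"confounder_filtered: {exc}")

    for covar in covariates or []:
        # One adjustment model per covariate (exposure + covariate jointly).
        try:
            mv_in = mvmr_harmonize(
                [exposure, covar], outcome, cfg, ambiguity_window, ld=ld
            )
            results = mvmr_ivw(mv_in)
            report.mvmr.append({
                "adjusted_for": covar.trait_label,
                "k": mv_in.j,
                "results": [r.to_dict() | {"exposure": r.extras["exposure"]}
                            for r in results],
            })
        except (EstimationError, MRKitError) as exc:
            report.errors.append(f"mvmr[{covar.trait_label}]: {exc}")

    try:
        final = [p for p in pairs if p.kept]
        kept_ids = {p.snp_id for p in final}
        r2_sum = sum(
            variance_explained(r, cfg.r2_formula)
            for r in clumped.records
            if r.snp_id in kept_ids and r.n is not None
        )
        n_out = pd.Series(
            [r.n for r in outcome.records if r.n is not None]
        ).median()
        case_rows = [
            r.n_cases / r.n for r in outcome.records
            if r.n_cases is not None and r.n
        ]
        kfrac = float(pd.Series(case_rows).median()) if case_rows else None
        if r2_sum > 0 and n_out and kfrac:
            pp = PowerParams(
                n_outcome=float(n_out), case_fraction=kfrac, r2_sum=r2_sum,
                or_target=power_or, power_target=power_target,
            )
            lo, hi = detectable_or(pp)
            report.power = {
                "r2_sum": r2_sum, "n_outcome": float(n_out),
                "case_fraction": kfrac, "alpha": pp.alpha,
                "or_target": power_or, "power": mr_power_binary(pp),
                "power_target": power_target,
                "detectable_or_low": lo, "detectable_or_high": hi,
            }
    except MRKitError as exc:
        report.errors.append(f"power: {exc}")

    if not report.counts_conserved():  # defensive: indicates an internal bug
        report.errors.append("stage counts not conserved")
    return report


# --------------------------------------------------------------------- files


class FileSpec(BaseModel):
    path: str
    label: str = "trait"
    trait_type: str = "continuous"
    delimiter: str = "\t"
    columns: Optional[Dict[str, str]] = None

    def colmap(self) -> ColumnMap:
        if self.columns:
            return ColumnMap(mapping=self.columns, delimiter=self.delimiter)
        return ColumnMap.identity(self.delimiter)


class RunConfig(BaseModel):
    """File-level configuration of :func:`run_pipeline` (YAML-friendly)."""

    exposure: FileSpec
    outcome: FileSpec
    ld_path: Optional[str] = None
    confounder_path: Optional[str] = None
    covariates: List[FileSpec] = Field(default_factory=list)
    selection: Dict[str, Any] = Field(default_factory=dict)
    ambiguity_window: float = 0.08
    methods: List[str] = Field(default_factory=lambda: list(DEFAULT_METHODS))
    seed: int = 0
    n_boot: int = 1000
    presso_sims: int = 1000
    out_dir: str = "mrkit_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Read inputs per the config, run the study, write report and tables."""
    for spec in [cfg.exposure, cfg.outcome, *cfg.covariates]:
        if not Path(spec.path).exists():
            raise ConfigurationError(f"input file not found: {spec.path}")

    exposure = read_summary_table(
        cfg.exposure.path, cfg.exposure.colmap(), cfg.exposure.label,
        cfg.exposure.trait_type,
    )
    outcome = read_summary_table(
        cfg.outcome.path, cfg.outcome.colmap(), cfg.outcome.label,
        cfg.outcome.trait_type,
    )
    ld = read_ld_table(cfg.ld_path) if cfg.ld_path else None
    conf = read_confounder_table(cfg.confounder_path) if cfg.confounder_path else None
    covars = [
        read_summary_table(s.path, s.colmap(), s.label, s.trait_type)
        for s in cfg.covariates
    ]

    selection = SelectionConfig(**cfg.selection)
    report = run_study(
        exposure, outcome, ld=ld, confounders=conf, covariates=covars,
        selection=selection, ambiguity_window=cfg.ambiguity_window,
        methods=cfg.methods, seed=cfg.seed, n_boot=cfg.n_boot,
        presso_sims=cfg.presso_sims,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.model_dump_json(indent=2))

    rows = []
    for name, block in (
        ("primary", report.primary), ("post_outlier", report.post_outlier),
        ("confounder_filtered", report.confounder_filtered),
        ("confounder_filtered_post_outlier",
         report.confounder_filtered_post_outlier),
    ):
        if block is None:
            continue
        for method, est in block.estimates.items():
            rows.append({"analysis": name, **est})
    pd.DataFrame(rows).to_csv(out / "estimates.tsv", sep="\t", index=False)

    # Re-derive the sensitivity tables for the primary instrument set.
    sig = select_significant(exposure, selection)
    clumped = clump(sig, ld, selection)
    pairs, _ = harmonize_datasets(clumped, outcome, cfg.ambiguity_window)
    model = MRModel.from_pairs(pairs)
    sens = out / "sens"
    sens.mkdir(exist_ok=True)
    if model.k >= 1:
        funnel_data(model).to_csv(sens / "funnel.tsv", sep="\t", index=False)
    if model.k >= 3:
        leave_one_out(model).to_frame().to_csv(
            sens / "loo.tsv", sep="\t", index=False
        )
    if model.k >= 4:
        presso(model, n_sim=cfg.presso_sims, seed=cfg.seed).to_frame().to_csv(
            sens / "presso.tsv", sep="\t", index=False
        )
    if model.k >= 2:
        (sens / "heterogeneity.json").write_text(
            json.dumps(cochran_q(model).to_dict(), indent=2)
        )
    logger.info("pipeline outputs written to %s", out)
    return report
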