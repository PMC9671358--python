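"""Seeded generator of two-sample GWAS summary statistics with known truth.

The generator works directly on the summary-statistic scale (no
individual-level genotypes): for standardized traits, a SNP with effect-allele
frequency f and true per-allele effect gamma has sampling SE
1/sqrt(2f(1−f)·N) in the exposure GWAS and, for a binary outcome analysed on
the log-odds scale with case fraction K, SE 1/sqrt(2f(1−f)·N·K·(1−K)).  The
true instrument effects are rescaled so they jointly explain a chosen fraction
of the exposure variance, the outcome effect is theta·gamma plus an optional
pleiotropic path, and the observed betas are normal draws around these truths.

Defaults mirror the motivating study design: 117 instruments for age at
menarche (N=218,796) against ischemic heart disease at FinnGen scale
(N=218,792, case fraction 0.145), causal OR 0.80 per exposure SD, and total
instrument R² of 4%.

Allele encodings of the outcome table can be randomly swapped or
strand-complemented (harmonization must undo this), a configurable fraction of
SNPs is palindromic, LD blocks add correlated proxy SNPs with an accompanying
LD table, and a confounder-association table marks a configurable subset of
instruments as confounded.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DomainError
from .io import ConfounderAssocTable, GWASRecord, LDTable, SummaryDataset

_NONPAL_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and b != {"A": "T", "T": "A", "C": "G", "G": "C"}[a]
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MIN_P = 1e-300


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-sample MR dataset.

    theta is the true causal effect of one exposure SD on the outcome
    log-odds; total_r2 the summed instrument variance explained;
    pleiotropy_mode one of none | balanced | directional | correlated
    (correlated draws the pleiotropic effect around
    pleiotropy_corr_scale·gamma_j, violating InSIDE).  ld_blocks, when set,
    is (n_blocks, snps_per_block, within_r2) and appends correlated proxy
    SNPs plus the matching LD table rows.
    """

    k_snps: int = 117
    n_exposure: float = 218_796
    n_outcome: float = 218_792
    case_fraction: float = 0.145
    theta: float = math.log(0.80)
    total_r2: float = 0.04
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.006
    pleiotropy_mean: float = -0.006
    pleiotropy_corr_scale: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    ld_blocks: Optional[tuple] = None
    palindromic_fraction: float = 0.05
    strand_flip_fraction: float = 0.0
    confounded_snps: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.total_r2 < 1.0):
            raise DomainError("total_r2 must lie in (0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError("case_fraction must lie in (0, 1)")
        for name in ("palindromic_fraction", "strand_flip_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "correlated"):
            raise DomainError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.k_snps < 1:
            raise DomainError("k_snps must be positive")


@dataclass
class SimulatedStudy:
    """Paired synthetic exposure/outcome datasets with their ground truth.

    ``truth`` holds theta, the per-SNP instrument effects gamma, the per-SNP
    pleiotropic effects alpha, MAFs, and any injected outliers.
    """

    exposure: SummaryDataset
    outcome: SummaryDataset
    truth: dict
    ld: LDTable = field(default_factory=LDTable)
    confounders: ConfounderAssocTable = field(default_factory=ConfounderAssocTable)
    config: Optional[SimulationConfig] = None


def fold_seed(seed: int, index: int) -> int:
    """Deterministically fold a replicate index into a base seed (< 2^31)."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0]
               % (2**31))


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P, 1.0)


def simulate_two_sample(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic study; identical output for identical config."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_snps

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    het = 2.0 * maf * (1.0 - maf)  # allele heterozygosity factor

    gamma = rng.normal(0.0, 1.0, size=k)
    scale2 = cfg.total_r2 / float(np.sum(het * gamma**2))
    gamma *= math.sqrt(scale2)

    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    beta_x = rng.normal(gamma, se_x)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=k)
    elif cfg.pleiotropy_mode == "directional":
        # directional pleiotropy is defined in the exposure-increasing
        # orientation (the frame Egger regression analyses), so its sign
        # follows the instrument's
        alpha = np.sign(gamma) * rng.normal(cfg.pleiotropy_mean,
                                            cfg.pleiotropy_sd, size=k)
    else:  # correlated: direct effects track instrument strength (breaks InSIDE)
        alpha = rng.normal(cfg.pleiotropy_corr_scale * gamma, cfg.pleiotropy_sd)

    kk = cfg.case_fraction
    se_y = 1.0 / np.sqrt(het * cfg.n_outcome * kk * (1.0 - kk))
    mu_y = cfg.theta * gamma + alpha
    beta_y = rng.normal(mu_y, se_y)

    p_x = _wald_p(beta_x, se_x)
    p_y = _wald_p(beta_y, se_y)

    # Allele pairs and effect-allele frequencies.
    is_pal = rng.random(k) < cfg.palindromic_fraction
    pair_idx = rng.integers(0, 8, size=k)
    pal_idx = rng.integers(0, 4, size=k)
    ea_is_minor = rng.random(k) < 0.5
    eaf = np.where(ea_is_minor, maf, 1.0 - maf)

    chrom = [str(j % 22 + 1) for j in range(k)]
    pos = [1_000_000 + (j // 22) * 20_000_000 for j in range(k)]
    ids = [f"rs{j + 1:06d}" for j in range(k)]

    n_cases = round(cfg.n_outcome * kk)
    exp_records, out_records = [], []
    flip = rng.random(k) < cfg.strand_flip_fraction
    flip_kind = rng.integers(0, 3, size=k)  # 0 swap, 1 complement, 2 both
    for j in range(k):
        ea, oa = (_PAL_PAIRS[pal_idx[j]] if is_pal[j] else _NONPAL_PAIRS[pair_idx[j]])
        exp_records.append(GWASRecord(
            snp_id=ids[j], effect_allele=ea, other_allele=oa,
            beta=float(beta_x[j]), se=float(se_x[j]), pval=float(p_x[j]),
            chrom=chrom[j], pos=pos[j], eaf=float(eaf[j]), n=cfg.n_exposure,
        ))
        yea, yoa, yb, yf = ea, oa, float(beta_y[j]), float(eaf[j])
        if flip[j]:
            kind = flip_kind[j]
            if kind in (0, 2):  # report the other allele as effect allele
                yea, yoa, yb, yf = yoa, yea, -yb, 1.0 - yf
            if kind in (1, 2):  # report on the opposite strand
                yea, yoa = _COMPLEMENT[yea], _COMPLEMENT[yoa]
        out_records.append(GWASRecord(
            snp_id=ids[j], effect_allele=yea, other_allele=yoa,
            beta=yb, se=float(se_y[j]), pval=float(p_y[j]),
            chrom=chrom[j], pos=pos[j], eaf=yf, n=cfg.n_outcome,
            n_cases=n_cases,
        ))

    ld = LDTable()
    if cfg.ld_blocks is not None:
        n_blocks, snps_per_block, within_r2 = cfg.ld_blocks
        n_blocks = min(n_blocks, k)
        for b in range(n_blocks):
            block = [ids[b]]
            g_idx = gamma[b]
            for i in range(snps_per_block - 1):
                pid = f"{ids[b]}_proxy{i + 1}"
                block.append(pid)
                g_p = math.sqrt(within_r2) * g_idx  # attenuated tagged effect
                sx = float(se_x[b])
                bxp = float(rng.normal(g_p, sx))
                syv = float(se_y[b])
                byp = float(rng.normal(cfg.theta * g_p, syv))
                for recs, bb, ss, nn, nc in (
                    (exp_records, bxp, sx, cfg.n_exposure, None),
                    (out_records, byp, syv, cfg.n_outcome, n_cases),
                ):
                    recs.append(GWASRecord(
                        snp_id=pid, effect_allele="A", other_allele="G",
                        beta=bb, se=ss,
                        pval=float(_wald_p(np.array([bb]), np.array([ss]))[0]),
                        chrom=chrom[b], pos=pos[b] + 50_000 * (i + 1),
                        eaf=float(eaf[b]), n=nn, n_cases=nc,
                    ))
            for a_i in range(len(block)):
                for b_i in range(a_i + 1, len(block)):
                    ld.add(block[a_i], block[b_i], within_r2)

    conf_rows = []
    for j in range(min(cfg.confounded_snps, k)):
        conf_rows.append((ids[j], "body mass index", 1e-12))
    # benign associations exercise the retain path
    for j in range(min(cfg.confounded_snps, k), min(cfg.confounded_snps + 3, k)):
        conf_rows.append((ids[j], "body mass index", 0.5))

    truth = {
        "theta": cfg.theta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "maf": maf.tolist(),
        "snp_ids": ids,
        "outliers": [],
    }
    exposure = SummaryDataset(
        "age_at_menarche", "continuous", exp_records, source="simulated"
    )
    outcome = SummaryDataset(
        "ischemic_heart_disease", "binary", out_records, source="simulated"
    )
    return SimulatedStudy(
        exposure=exposure, outcome=outcome, truth=truth, ld=ld,
        confounders=ConfounderAssocTable(conf_rows), config=cfg,
    )


def inject_outlier(
    study: SimulatedStudy, snp_index: int, offset_in_se_units: float
) -> SimulatedStudy:
    """Return a copy with one outcome beta shifted by offset·se (pleiotropic
    outlier); the truth records the injection."""
    if not (0 <= snp_index < len(study.outcome.records)):
        raise IndexError(f"snp_index {snp_index} out of range")
    out = copy.deepcopy(study)
    rec = out.outcome.records[snp_index]
    rec.beta += offset_in_se_units * rec.se
    out.truth["outliers"].append(
        {"snp_id": rec.snp_id, "offset_in_se_units": offset_in_se_units}
    )
    return out
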