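"""Instrument selection: significance screen, LD clumping, strength metrics.

Instruments for the exposure must be genome-wide significant (p < 5e-8),
common (MAF > 0.01), mutually independent (greedy clumping at r² <= 0.001
within a 10 Mb window), and strong (F > 10).  All thresholds are strict
inequalities and configurable through :class:`SelectionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .exceptions import ConfigurationError, DomainError
from .io import ConfounderAssocTable, GWASRecord, LDTable, SummaryDataset


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    p_threshold : genome-wide significance cut-off (keep p strictly below).
    maf_min     : keep SNPs with minor-allele frequency strictly above this.
    clump_r2_max: LD pruning threshold; known r² above this removes a SNP.
    clump_window_kb : genomic window (kb) within which LD pruning applies.
    f_min       : conventional weak-instrument F threshold (reported, and
                  applied by :func:`filter_weak`).
    strict_ld   : drop in-window pairs with *unknown* LD instead of keeping
                  them (no bundled reference panel can measure them).
    r2_formula  : "reduced" (standard beta²/(beta²+N se²)) or "verbatim"
                  (audit-only; see :func:`variance_explained`).
    """

    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2_max: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    strict_ld: bool = False
    r2_formula: str = "reduced"

    def __post_init__(self):
        if not (self.p_threshold > 0 and self.maf_min > 0 and self.f_min >= 0):
            raise ConfigurationError("selection thresholds must be positive")
        if not (0.0 < self.clump_r2_max < 1.0):
            raise ConfigurationError("clump_r2_max must lie in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be positive")
        if self.r2_formula not in ("reduced", "verbatim"):
            raise ConfigurationError("r2_formula must be 'reduced' or 'verbatim'")


@dataclass(frozen=True)
class InstrumentStrength:
    """Variance explained and F-statistic for one instrument."""

    snp_id: str
    r2_explained: float
    f_stat: float


def select_significant(dataset: SummaryDataset, cfg: SelectionConfig) -> SummaryDataset:
    """Keep records with p < p_threshold and MAF > maf_min (strict), in order.

    Records without an EAF cannot pass the MAF screen and are dropped.
    """
    kept = []
    for r in dataset.records:
        if not (r.pval < cfg.p_threshold):
            continue
        if r.maf is None or not (r.maf > cfg.maf_min):
            continue
        kept.append(r)
    return replace(dataset, records=kept, drop_tally=dataset.drop_tally.copy())


def variance_explained(record: GWASRecord, formula: str = "reduced") -> float:
    """Fraction of exposure variance explained by one SNP.

    The standard approximation for a standardized trait is

        R² = beta² / (beta² + N · se²),

    which is the 2·EAF·(1−EAF)·beta² form with the allele-frequency factor
    cancelled between numerator and denominator (se² ≈ 1/(2·EAF·(1−EAF)·N)).
    ``formula="verbatim"`` instead evaluates
    beta²/(beta² + se·N·beta²) = 1/(1 + se·N); it exists only to audit
    sources that print that expression and should not be used for analysis.
    """
    if record.n is None or record.n <= 2:
        raise DomainError(f"{record.snp_id}: sample size n must exceed 2")
    if not record.se > 0:
        raise DomainError(f"{record.snp_id}: se must be positive")
    b2 = record.beta ** 2
    if formula == "verbatim":
        return b2 / (b2 + record.se * record.n * b2) if b2 > 0 else 0.0
    return b2 / (b2 + record.n * record.se ** 2)


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F-statistic, F = R²·(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError("r2 must lie in [0, 1)")
    if n <= 2:
        raise DomainError("n must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strength(record: GWASRecord, formula: str = "reduced") -> InstrumentStrength:
    r2 = variance_explained(record, formula=formula)
    return InstrumentStrength(record.snp_id, r2, f_statistic(r2, record.n))


def filter_weak(dataset: SummaryDataset, cfg: SelectionConfig) -> SummaryDataset:
    """Drop instruments with F-statistic not exceeding ``cfg.f_min``."""
    kept = [
        r for r in dataset.records
        if instrument_strength(r, cfg.r2_formula).f_stat > cfg.f_min
    ]
    return replace(dataset, records=kept, drop_tally=dataset.drop_tally.copy())


def clump(
    dataset: SummaryDataset,
    ld: Optional[LDTable],
    cfg: SelectionConfig,
) -> SummaryDataset:
    """Greedy LD clumping: keep the smallest-p representative of each region.

    SNPs are visited in ascending p (ties broken by (chrom, pos) then id so
    results are deterministic); a SNP is rejected when some already-accepted
    SNP is on the same chromosome within ``clump_window_kb`` and their known
    r² exceeds ``clump_r2_max``.  Unknown in-window LD keeps the SNP (logged)
    unless ``strict_ld``.  The returned dataset preserves the input record
    order and carries ``.clump_removals`` as (removed_snp, index_snp) pairs.
    """
    recs = dataset.records
    have_pos = all(r.chrom is not None and r.pos is not None for r in recs)
    if ld is None and not have_pos:
        raise ConfigurationError(
            "clumping needs chrom/pos on every record or an LD table; "
            "supply one or the other"
        )
    window_bp = cfg.clump_window_kb * 1000.0

    def sort_key(r: GWASRecord):
        return (r.pval, r.chrom or "", r.pos if r.pos is not None else 0, r.snp_id)

    accepted: list = []
    removals: list = []
    for r in sorted(recs, key=sort_key):
        index_snp = None
        for a in accepted:
            in_window = True  # unknown positions: rely on r² alone
            if (
                r.chrom is not None and a.chrom is not None
                and r.pos is not None and a.pos is not None
            ):
                in_window = (r.chrom == a.chrom) and abs(r.pos - a.pos) <= window_bp
            if not in_window:
                continue
            r2 = ld.lookup(r.snp_id, a.snp_id) if ld is not None else None
            if r2 is None:
                if cfg.strict_ld:
                    index_snp = a
                    break
                continue  # unmeasured pair: treated as independent
            if r2 > cfg.clump_r2_max:
                index_snp = a
                break
        if index_snp is None:
            accepted.append(r)
        else:
            removals.append((r.snp_id, index_snp.snp_id))

    keep_ids = {r.snp_id for r in accepted}
    out = replace(
        dataset,
        records=[r for r in recs if r.snp_id in keep_ids],
        drop_tally=dataset.drop_tally.copy(),
    )
    out.clump_removals = removals
    return out


def filter_confounders(
    instruments: SummaryDataset,
    table: ConfounderAssocTable,
    p_threshold: float = 5e-8,
) -> SummaryDataset:
    """Drop instruments significantly associated with any listed confounder.

    An instrument is removed when at least one table row gives it an
    association p strictly below ``p_threshold``.  The returned dataset
    carries ``.confounder_drops`` mapping dropped SNP id -> offending traits.
    """
    drops: dict = {}
    kept = []
    for r in instruments.records:
        offending = [t for t, p in table.associations(r.snp_id) if p < p_threshold]
        if offending:
            drops[r.snp_id] = offending
        else:
            kept.append(r)
    out = replace(instruments, records=kept, drop_tally=instruments.drop_tally.copy())
    out.confounder_drops = drops
    return out
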