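"""Harmonization of exposure and outcome effects to a common effect allele.

Two summary datasets report the same SNP, but possibly with the effect and
other alleles swapped, on opposite strands, or both.  Harmonization re-orients
the outcome record so both betas refer to the exposure's effect allele.
Palindromic SNPs (A/T or C/G) carry no strand information in their alleles and
are oriented by allele-frequency concordance, or dropped when either frequency
is too close to 0.5 to call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .io import GWASRecord, SummaryDataset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Harmonization dispositions.
DIRECT = "direct"
SWAPPED = "swapped"
STRAND_FLIPPED = "strand_flipped"
STRAND_FLIPPED_SWAPPED = "strand_flipped_swapped"
DROPPED_PALINDROMIC = "dropped_palindromic_ambiguous"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING_OUTCOME = "dropped_missing_outcome"
DROPPED_DUPLICATE = "dropped_duplicate"

ALL_STATUSES = (
    DIRECT, SWAPPED, STRAND_FLIPPED, STRAND_FLIPPED_SWAPPED,
    DROPPED_PALINDROMIC, DROPPED_INCOMPATIBLE,
    DROPPED_MISSING_OUTCOME, DROPPED_DUPLICATE,
)
KEPT_STATUSES = (DIRECT, SWAPPED, STRAND_FLIPPED, STRAND_FLIPPED_SWAPPED)


@dataclass
class HarmonizedPair:
    """Exposure/outcome effects aligned to the exposure's effect allele."""

    snp_id: str
    beta_x: float = float("nan")
    se_x: float = float("nan")
    eaf_x: Optional[float] = None
    beta_y: float = float("nan")
    se_y: float = float("nan")
    eaf_y: Optional[float] = None
    status: str = DIRECT

    @property
    def kept(self) -> bool:
        return self.status in KEPT_STATUSES


@dataclass
class HarmonizationReport:
    """Per-status counts and the dropped SNPs with reasons."""

    counts: Counter = field(default_factory=Counter)
    dropped: list = field(default_factory=list)  # (snp_id, status)
    offered: int = 0

    @property
    def kept(self) -> int:
        return sum(self.counts[s] for s in KEPT_STATUSES)

    def conserved(self) -> bool:
        return sum(self.counts.values()) == self.offered


def classify_snp(effect_allele: str, other_allele: str) -> str:
    """``"palindromic"`` when the allele pair is A/T or C/G, else ``"non_palindromic"``."""
    pair = {effect_allele, other_allele}
    if pair in ({"A", "T"}, {"C", "G"}):
        return "palindromic"
    return "non_palindromic"


def _is_palindromic(ea: str, oa: str) -> bool:
    return classify_snp(ea, oa) == "palindromic"


def harmonize_pair(
    x: GWASRecord, y: GWASRecord, ambiguity_window: float = 0.08
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    Resolution order: direct allele match; swapped match (negate beta_y and
    flip eaf_y); strand-complemented match, direct then swapped.  Palindromic
    SNPs skip allele matching entirely (their complement equals their swap)
    and are oriented so the minor allele agrees across datasets — provided
    both EAFs lie outside [0.5−w, 0.5+w]; otherwise the pair is dropped as
    ambiguous.  Alleles matching under no transformation are incompatible.
    """
    if x.snp_id != y.snp_id:
        raise ValueError(f"snp_id mismatch: {x.snp_id!r} vs {y.snp_id!r}")

    out = HarmonizedPair(
        snp_id=x.snp_id, beta_x=x.beta, se_x=x.se, eaf_x=x.eaf,
        beta_y=y.beta, se_y=y.se, eaf_y=y.eaf,
    )
    xe, xo = x.effect_allele, x.other_allele
    ye, yo = y.effect_allele, y.other_allele

    if _is_palindromic(xe, xo):
        if {xe, xo} != {ye, yo}:
            out.status = DROPPED_INCOMPATIBLE
            return out
        w = ambiguity_window + 1e-12  # tolerance so the stated band is inclusive
        if (
            x.eaf is None or y.eaf is None
            or abs(x.eaf - 0.5) <= w or abs(y.eaf - 0.5) <= w
        ):
            out.status = DROPPED_PALINDROMIC
            return out
        if (x.eaf < 0.5) == (y.eaf < 0.5):
            out.status = DIRECT
        else:
            out.beta_y = -y.beta
            out.eaf_y = 1.0 - y.eaf
            out.status = SWAPPED
        return out

    if (ye, yo) == (xe, xo):
        out.status = DIRECT
        return out
    if (ye, yo) == (xo, xe):
        out.beta_y = -y.beta
        out.eaf_y = None if y.eaf is None else 1.0 - y.eaf
        out.status = SWAPPED
        return out
    ce, co = _COMPLEMENT[ye], _COMPLEMENT[yo]
    if (ce, co) == (xe, xo):
        out.status = STRAND_FLIPPED
        return out
    if (ce, co) == (xo, xe):
        out.beta_y = -y.beta
        out.eaf_y = None if y.eaf is None else 1.0 - y.eaf
        out.status = STRAND_FLIPPED_SWAPPED
        return out

    out.status = DROPPED_INCOMPATIBLE
    return out


def harmonize_datasets(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ambiguity_window: float = 0.08,
) -> tuple:
    """Harmonize every exposure instrument against the outcome dataset.

    Instruments absent from the outcome are ``dropped_missing_outcome``;
    SNP ids occurring more than once in either dataset are
    ``dropped_duplicate`` (ambiguous extraction); the rest go through
    :func:`harmonize_pair`.  Returns ``(pairs, report)`` with the report's
    status counts summing to the number of instruments offered.
    """
    x_counts = Counter(r.snp_id for r in exposure.records)
    y_counts = Counter(r.snp_id for r in outcome.records)
    y_by_id = {r.snp_id: r for r in outcome.records}

    report = HarmonizationReport(offered=len(exposure.records))
    pairs: list = []
    for x in exposure.records:
        if x_counts[x.snp_id] > 1 or y_counts.get(x.snp_id, 0) > 1:
            pair = HarmonizedPair(snp_id=x.snp_id, status=DROPPED_DUPLICATE)
        elif x.snp_id not in y_by_id:
            pair = HarmonizedPair(snp_id=x.snp_id, status=DROPPED_MISSING_OUTCOME)
        else:
            pair = harmonize_pair(x, y_by_id[x.snp_id], ambiguity_window)
        report.counts[pair.status] += 1
        if not pair.kept:
            report.dropped.append((pair.snp_id, pair.status))
        pairs.append(pair)
    return pairs, report
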