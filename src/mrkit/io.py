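"""Reading, validating and writing GWAS summary-statistics tables.

GWAS summary statistics arrive as delimited text with heterogeneous column
names; a :class:`ColumnMap` translates a source file's header into the
canonical field names used throughout the package.  Readers never emit a
record that violates the :class:`GWASRecord` invariants: malformed rows are
dropped and tallied, never silently repaired.

Auxiliary tables — pairwise LD (r²) and SNP–confounder associations
(PhenoScanner-style exports) — use fixed three-column layouts.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Canonical field order of a summary-statistics record.
ALL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
)

#: Fields a column map must always provide.
REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

_NA_DEFAULT = ("", "NA", "NaN", "nan", ".", "None")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical record fields to source-file column names.

    Parameters
    ----------
    mapping:
        ``{canonical_field: source_column}``.  Fields absent from the mapping
        are treated as absent from the file (allowed only for optional
        fields).  Defaults to the identity mapping over all fields.
    delimiter:
        Field separator, tab by default.
    na_tokens:
        Strings treated as missing values.
    """

    mapping: dict = field(default_factory=lambda: {f: f for f in ALL_FIELDS})
    delimiter: str = "\t"
    na_tokens: tuple = _NA_DEFAULT

    def __post_init__(self):
        missing = [f for f in REQUIRED_FIELDS if f not in self.mapping]
        if missing:
            raise ConfigurationError(
                "column map must provide required fields: missing "
                + ", ".join(missing)
            )
        unknown = [f for f in self.mapping if f not in ALL_FIELDS]
        if unknown:
            raise ConfigurationError(f"unknown record fields in column map: {unknown}")

    @classmethod
    def identity(cls, delimiter: str = "\t") -> "ColumnMap":
        return cls(delimiter=delimiter)


@dataclass
class GWASRecord:
    """One SNP's association summary.

    ``beta`` is the per-allele effect of ``effect_allele``; for binary traits
    it is on the log-odds scale.  ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None
    n_cases: Optional[float] = None

    def problems(self) -> list:
        """Return invariant violations (empty list for a valid record)."""
        out = []
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_BASES or oa not in VALID_BASES:
            out.append("allele_not_single_base")
        elif ea == oa:
            out.append("identical_alleles")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append("eaf_out_of_range")
        if not (self.se > 0) or not math.isfinite(self.se):
            out.append("nonpositive_se")
        if not (0.0 < self.pval <= 1.0):
            out.append("pval_out_of_range")
        if not math.isfinite(self.beta):
            out.append("nonfinite_beta")
        if self.n is not None and not self.n > 1:
            out.append("n_too_small")
        if self.n_cases is not None and self.n_cases < 0:
            out.append("negative_n_cases")
        return out

    @property
    def maf(self) -> Optional[float]:
        """Minor-allele frequency ``min(eaf, 1-eaf)``; None when eaf is absent."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`GWASRecord` for one trait.

    ``trait_type`` is ``"continuous"`` or ``"binary"``; binary-trait betas are
    log odds ratios.  ``drop_tally`` records rows a reader discarded, keyed by
    reason.
    """

    trait_label: str
    trait_type: str
    records: list
    source: str = ""
    drop_tally: Counter = field(default_factory=Counter)

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be continuous|binary, got {self.trait_type!r}"
            )
        ids = [r.snp_id for r in self.records]
        dupes = {i for i, c in Counter(ids).items() if c > 1}
        if dupes:
            # Kept (not dropped) so harmonization can classify them explicitly.
            logger.warning(
                "%s: %d duplicated snp_id(s): %s",
                self.trait_label, len(dupes), sorted(dupes)[:5],
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GWASRecord]:
        return iter(self.records)

    def ids(self) -> list:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> Optional[GWASRecord]:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def subset(self, keep_ids: Iterable[str]) -> "SummaryDataset":
        keep = set(keep_ids)
        return replace(
            self,
            records=[r for r in self.records if r.snp_id in keep],
            drop_tally=Counter(),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{f: getattr(r, f) for f in ALL_FIELDS} for r in self.records]
        return pd.DataFrame(rows, columns=list(ALL_FIELDS))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, trait_label: str, trait_type: str, source: str = ""
    ) -> "SummaryDataset":
        recs = []
        for row in df.itertuples(index=False):
            d = {f: getattr(row, f, None) for f in ALL_FIELDS}
            recs.append(_record_from_raw(d))
        return cls(trait_label, trait_type, recs, source=source)


def _coerce_float(v):
    """Required numeric fields: missing or unparseable becomes NaN (invalid)."""
    if v is None:
        return math.nan
    try:
        return float(v)
    except (TypeError, ValueError):
        return math.nan


def _record_from_raw(d: dict) -> GWASRecord:
    pos = d.get("pos")
    if pos is not None and not (isinstance(pos, float) and math.isnan(pos)):
        pos = int(float(pos))
    else:
        pos = None
    chrom = d.get("chrom")
    if chrom is not None and not (isinstance(chrom, float) and math.isnan(chrom)):
        chrom = str(chrom).strip()
        if chrom.endswith(".0"):  # numeric chromosome read back as float
            chrom = chrom[:-2]
    else:
        chrom = None

    def opt(name):
        v = _coerce_float(d.get(name))
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    return GWASRecord(
        snp_id=str(d["snp_id"]).strip(),
        effect_allele=str(d.get("effect_allele", "")).strip().upper(),
        other_allele=str(d.get("other_allele", "")).strip().upper(),
        beta=_coerce_float(d.get("beta")),
        se=_coerce_float(d.get("se")),
        pval=_coerce_float(d.get("pval")),
        chrom=chrom,
        pos=pos,
        eaf=opt("eaf"),
        n=opt("n"),
        n_cases=opt("n_cases"),
    )


def read_summary_table(
    path, colmap: Optional[ColumnMap] = None, trait_label: str = "trait",
    trait_type: str = "continuous",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    Rows violating the record invariants (non-ACGT or identical alleles,
    non-positive SE, p outside (0,1], EAF outside [0,1]) are dropped and
    counted in ``dataset.drop_tally``.  Alleles are upper-cased.
    """
    colmap = colmap or ColumnMap.identity()
    try:
        df = pd.read_csv(
            path,
            sep=colmap.delimiter,
            dtype=str,
            na_values=list(colmap.na_tokens),
            keep_default_na=False,
            comment="#",
        )
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}") from None
    if df.empty and df.columns.empty:
        raise InputError(f"empty summary-statistics file: {path}")

    missing = [
        f for f in REQUIRED_FIELDS if colmap.mapping[f] not in df.columns
    ]
    if missing:
        cols = ", ".join(colmap.mapping[f] for f in missing)
        raise ConfigurationError(
            f"{path}: required column(s) not found: {cols}"
        )

    tally: Counter = Counter()
    records = []
    inv_present = {
        f: c for f, c in colmap.mapping.items() if c in df.columns
    }
    for _, row in df.iterrows():
        raw = {f: row[c] if pd.notna(row[c]) else None for f, c in inv_present.items()}
        rec = _record_from_raw(raw)
        probs = rec.problems()
        if probs:
            tally[probs[0]] += 1
            continue
        records.append(rec)
    if tally:
        logger.info("%s: dropped %d malformed row(s): %s", path, sum(tally.values()),
                    dict(tally))
    ds = SummaryDataset(trait_label, trait_type, records, source=str(path))
    ds.drop_tally = tally
    return ds


_FLOAT_FMT = "%.17g"


def write_summary_table(dataset: SummaryDataset, path, colmap: Optional[ColumnMap] = None):
    """Write a dataset as delimited text; round-trips at full float precision.

    Optional columns that are absent for every record are omitted.
    """
    colmap = colmap or ColumnMap.identity()
    df = dataset.to_frame()
    for col in ("chrom", "pos", "eaf", "n", "n_cases"):
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=[col])
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype("Int64")
    if "n" in df.columns and (df["n"].dropna() == df["n"].dropna().round()).all():
        df["n"] = df["n"].astype("Int64")
    if "n_cases" in df.columns:
        df["n_cases"] = df["n_cases"].astype("Int64")
    df = df.rename(columns={f: c for f, c in colmap.mapping.items()})
    df.to_csv(path, sep=colmap.delimiter, index=False, float_format=_FLOAT_FMT)


class LDTable:
    """Pairwise LD (r²) lookups, symmetric in the SNP pair.

    An absent pair is *unknown* (``lookup`` returns ``None``), which is
    distinct from independence (r²=0): clumping must not treat unmeasured
    pairs as independent without saying so.  Duplicate pairs keep the maximum
    r² (conservative for clumping) with a logged warning.
    """

    def __init__(self, rows: Optional[Iterable[tuple]] = None):
        self._r2: dict = {}
        self.n_dropped = 0
        for a, b, r2 in rows or ():
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float):
        try:
            r2 = float(r2)
        except (TypeError, ValueError):
            self.n_dropped += 1
            return
        if not (0.0 <= r2 <= 1.0) or a == b:
            self.n_dropped += 1
            return
        k = self._key(str(a), str(b))
        if k in self._r2 and self._r2[k] != r2:
            logger.warning("duplicate LD pair %s with differing r2; keeping max", k)
            r2 = max(r2, self._r2[k])
        self._r2[k] = r2

    def lookup(self, a: str, b: str) -> Optional[float]:
        """r² for the pair, or ``None`` when the pair is unmeasured."""
        return self._r2.get(self._key(str(a), str(b)))

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def read_ld_table(path, delimiter: str = "\t") -> LDTable:
    """Read a 3-column (snp_a, snp_b, r2) table; bad rows dropped and counted."""
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty LD table: {path}") from None
    if df.shape[1] < 3:
        raise InputError(f"LD table needs 3 columns (snp_a, snp_b, r2): {path}")
    table = LDTable()
    for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
        table.add(a, b, r2)
    if table.n_dropped:
        logger.info("%s: dropped %d invalid LD row(s)", path, table.n_dropped)
    return table


def write_ld_table(table: LDTable, path, delimiter: str = "\t"):
    table.to_frame().to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


class ConfounderAssocTable:
    """SNP–confounder association p-values (PhenoScanner-style export)."""

    def __init__(self, rows: Optional[Iterable[tuple]] = None):
        self.rows: list = []
        self.n_dropped = 0
        for snp_id, trait, pval in rows or ():
            try:
                p = float(pval)
            except (TypeError, ValueError):
                self.n_dropped += 1
                continue
            if not (0.0 < p <= 1.0):
                self.n_dropped += 1
                continue
            self.rows.append((str(snp_id), str(trait), p))

    def associations(self, snp_id: str):
        """All (trait_label, pval) rows for a SNP."""
        return [(t, p) for s, t, p in self.rows if s == snp_id]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["snp_id", "trait_label", "pval"])


def read_confounder_table(path, delimiter: str = "\t") -> ConfounderAssocTable:
    """Read a 3-column (snp_id, trait_label, pval) table; bad rows counted."""
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty confounder table: {path}") from None
    if df.shape[1] < 3:
        raise InputError(
            f"confounder table needs 3 columns (snp_id, trait_label, pval): {path}"
        )
    table = ConfounderAssocTable(df.iloc[:, :3].itertuples(index=False))
    if table.n_dropped:
        logger.info("%s: dropped %d invalid confounder row(s)", path, table.n_dropped)
    return table


def write_confounder_table(table: ConfounderAssocTable, path, delimiter: str = "\t"):
    table.to_frame().to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)
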