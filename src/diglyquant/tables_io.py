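"""Reading, validation and filtering of MaxQuant-dialect quantification tables.

The pipeline consumes finished search-engine output: a proteinGroups-like
table (one row per protein group, raw normalized H/L ratios per replicate)
and a GlyGly-sites-like table (one row per candidate ubiquitination site).
Ratios are ingested on the raw H/L scale and log2-transformed exactly once
here; everything downstream works in log2 units.  Row exclusion follows the
standard diGly workflow: contaminant and reversed-database hits are removed,
and any site whose GG remnant sits on a peptide C-terminal lysine with a
localization probability better than 50% is treated as a tryptic artifact
and dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "ProteinRecord",
    "PoolingMap",
    "ColumnMap",
    "SchemaError",
    "read_protein_table",
    "read_site_table",
    "write_protein_table",
    "write_site_table",
    "filter_rows",
    "pooling_map",
    "read_fasta",
    "write_fasta",
]

FLAG = "+"  # MaxQuant marks boolean columns with "+"


class SchemaError(ValueError):
    """A mandatory column is missing or a table is structurally unusable."""


@dataclass(frozen=True)
class SiteRecord:
    """One quantified diGly site (collapsed to its best-localized peptide)."""

    site_id: str
    protein_id: str
    position: int
    residue: str
    log2_hl: dict  # replicate name -> log2(H/L); absent replicates omitted
    localization_prob: float
    is_cterm_gg: bool = False
    contaminant: bool = False
    reverse: bool = False

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not (0.0 <= self.localization_prob <= 1.0):
            raise ValueError(
                f"localization_prob must lie in [0, 1], got {self.localization_prob}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group keyed by its leading razor protein accession."""

    protein_id: str
    log2_hl: dict
    intensity: float | None = None
    contaminant: bool = False
    reverse: bool = False

    def __post_init__(self):
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PoolingMap:
    """Non-contiguous assignment of chromatographic source fractions to pools."""

    n_source: int
    n_pools: int
    assignment: dict  # source fraction (1-based) -> pool index (1-based)

    def members(self, pool: int) -> list[int]:
        return sorted(f for f, p in self.assignment.items() if p == pool)


@dataclass(frozen=True)
class ColumnMap:
    """Column names of the table dialect; defaults follow MaxQuant naming."""

    protein_id: str = "Leading razor protein"
    position: str = "Position"
    residue: str = "Amino acid"
    localization_prob: str = "Localization prob"
    ratio_prefix: str = "Ratio H/L normalized"
    intensity: str = "Intensity"
    contaminant: str = "Potential contaminant"
    reverse: str = "Reverse"
    cterm_gg: str = "GG on C-term K"
    site_id: str = "Site ID"


def _ratio_columns(columns: Iterable[str], prefix: str) -> list[str]:
    return [c for c in columns if c.startswith(prefix + " ") or c == prefix]

def _replicate_name(column: str, prefix: str) -> str:
    tail = column[len(prefix):].strip()
    return tail if tail else "1"


def _parse_log2_ratios(row: pd.Series, ratio_cols: Sequence[str], prefix: str,
                       failures: list) -> dict:
    """Raw H/L -> log2; unparseable or non-positive entries become absent."""
    out = {}
    for col in ratio_cols:
        raw = row[col]
        try:
            val = float(raw)
        except (TypeError, ValueError):
            failures.append((row.name, col))
            continue
        if not math.isfinite(val) or val <= 0:
            continue
        out[_replicate_name(col, prefix)] = math.log2(val)
    return out


def _require(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise SchemaError(f"table {path} contains no data rows")
    return df


def read_protein_table(path, colmap: ColumnMap = ColumnMap()) -> list[ProteinRecord]:
    """Parse a proteinGroups-like tab-delimited table into ProteinRecords.

    Numeric parse failures become absent values (counted but tolerated);
    a missing mandatory column raises :class:`SchemaError`.
    """
    df = _read_table(path)
    _require(df, [colmap.protein_id])
    ratio_cols = _ratio_columns(df.columns, colmap.ratio_prefix)
    if not ratio_cols:
        raise SchemaError(f"missing mandatory column(s): {colmap.ratio_prefix} *")
    failures: list = []
    records = []
    for _, row in df.iterrows():
        log2_hl = _parse_log2_ratios(row, ratio_cols, colmap.ratio_prefix, failures)
        intensity = None
        if colmap.intensity in df.columns:
            try:
                intensity = float(row[colmap.intensity])
            except (TypeError, ValueError):
                intensity = None
            if intensity is not None and not math.isfinite(intensity):
                intensity = None
        records.append(ProteinRecord(
            protein_id=row[colmap.protein_id],
            log2_hl=log2_hl,
            intensity=intensity,
            contaminant=row.get(colmap.contaminant, "") == FLAG,
            reverse=row.get(colmap.reverse, "") == FLAG,
        ))
    return records


def read_site_table(path, colmap: ColumnMap = ColumnMap()) -> list[SiteRecord]:
    """Parse a GlyGly-sites-like tab-delimited table into SiteRecords."""
    df = _read_table(path)
    _require(df, [colmap.protein_id, colmap.position, colmap.residue,
                  colmap.localization_prob])
    ratio_cols = _ratio_columns(df.columns, colmap.ratio_prefix)
    if not ratio_cols:
        raise SchemaError(f"missing mandatory column(s): {colmap.ratio_prefix} *")
    failures: list = []
    records = []
    for _, row in df.iterrows():
        log2_hl = _parse_log2_ratios(row, ratio_cols, colmap.ratio_prefix, failures)
        protein_id = row[colmap.protein_id]
        position = int(float(row[colmap.position]))
        site_id = row.get(colmap.site_id) or f"{protein_id}_{row[colmap.residue]}{position}"
        records.append(SiteRecord(
            site_id=site_id,
            protein_id=protein_id,
            position=position,
            residue=row[colmap.residue],
            log2_hl=log2_hl,
            localization_prob=float(row[colmap.localization_prob]),
            is_cterm_gg=row.get(colmap.cterm_gg, "") == FLAG,
            contaminant=row.get(colmap.contaminant, "") == FLAG,
            reverse=row.get(colmap.reverse, "") == FLAG,
        ))
    return records


def _fmt_ratio(log2_value: float) -> str:
    return repr(2.0 ** log2_value)


def write_protein_table(records: Sequence[ProteinRecord], path,
                        colmap: ColumnMap = ColumnMap(),
                        replicates: Sequence[str] = ("1", "2")) -> None:
    rows = []
    for r in records:
        row = {colmap.protein_id: r.protein_id,
               colmap.intensity: "" if r.intensity is None else repr(r.intensity),
               colmap.contaminant: FLAG if r.contaminant else "",
               colmap.reverse: FLAG if r.reverse else ""}
        for rep in replicates:
            col = f"{colmap.ratio_prefix} {rep}"
            row[col] = _fmt_ratio(r.log2_hl[rep]) if rep in r.log2_hl else "NaN"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_site_table(records: Sequence[SiteRecord], path,
                     colmap: ColumnMap = ColumnMap(),
                     replicates: Sequence[str] = ("1", "2")) -> None:
    rows = []
    for r in records:
        row = {colmap.site_id: r.site_id,
               colmap.protein_id: r.protein_id,
               colmap.position: str(r.position),
               colmap.residue: r.residue,
               colmap.localization_prob: repr(r.localization_prob),
               colmap.cterm_gg: FLAG if r.is_cterm_gg else "",
               colmap.contaminant: FLAG if r.contaminant else "",
               colmap.reverse: FLAG if r.reverse else ""}
        for rep in replicates:
            col = f"{colmap.ratio_prefix} {rep}"
            row[col] = _fmt_ratio(r.log2_hl[rep]) if rep in r.log2_hl else "NaN"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_rows(records):
    """Apply the row-exclusion rules; idempotent by construction.

    Drops contaminant and reverse rows for both record kinds.  For sites,
    additionally drops C-terminal-lysine GG remnants with localization
    probability strictly above 0.5, and any site not on a lysine.
    """
    kept = []
    for r in records:
        if r.contaminant or r.reverse:
            continue
        if isinstance(r, SiteRecord):
            if r.is_cterm_gg and r.localization_prob > 0.5:
                continue
            if r.residue != "K":
                continue
        kept.append(r)
    return kept


def pooling_map(n_source: int, n_pools: int) -> PoolingMap:
    """Non-contiguous interleaved pooling of source fractions.

    Source fraction f goes to pool ((f-1) mod n_pools) + 1, so consecutive
    chromatographic fractions land in different pools and every pool samples
    the whole gradient.  n_pools must divide n_source.
    """
    if n_pools <= 0 or n_source <= 0:
        raise ValueError("n_source and n_pools must be positive")
    if n_source % n_pools != 0:
        raise ValueError(
            f"n_pools={n_pools} does not divide n_source={n_source}")
    assignment = {f: ((f - 1) % n_pools) + 1 for f in range(1, n_source + 1)}
    return PoolingMap(n_source=n_source, n_pools=n_pools, assignment=assignment)


def read_fasta(path) -> dict:
    """FASTA -> {accession: sequence} via Biopython."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
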