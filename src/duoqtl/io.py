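"""Readers and writers for every on-disk table the pipeline touches.

Conventions shared by all tables:

* Genomic positions are 1-based; marker/bin intervals are 1-based and
  inclusive on both ends, and marker ids are ``{chrom}_{start}_{end}``.
* Missing values are serialized as the literal string ``NA``.
* Genotype, count and marker tables are tab-separated; phenotype tables are
  comma-separated (the usual trait-sheet provenance).
* Lines starting with ``#`` are metadata comments (seed, package version)
  and are ignored by every reader.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NA = "NA"
NUCLEOTIDES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """A file does not have the expected structure (e.g. missing column)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries its coordinates."""


def _comment_lines(metadata: dict | None) -> list[str]:
    if not metadata:
        return []
    return ["# " + " ".join(f"{k}={v}" for k, v in metadata.items())]


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

ALLELE_COUNT_COLUMNS = ("line_id", "chrom", "pos", "A", "C", "G", "T")


@dataclass
class AlleleCountResult:
    """Parsed allele-count table plus the rows that violated invariants.

    ``records`` has columns line_id, chrom, pos, A, C, G, T with integer
    counts; ``rejected`` is a list of ``(file_line_number, reason)`` so that
    rows_in == rows_accepted + rows_rejected always holds.
    """

    records: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)


def read_allele_counts(path: str | Path) -> AlleleCountResult:
    """Read a parsed-mpileup style per-site nucleotide count table.

    Tab-separated with header ``line_id chrom pos A C G T``. Rows violating
    the positional invariants (pos < 1, negative count, duplicate
    (line_id, chrom, pos)) are rejected and reported with their 1-based file
    line numbers rather than silently dropped. A missing column raises
    :class:`FormatError`; a non-integer count raises :class:`ParseError`.
    """
    path = Path(path)
    rows: list[tuple] = []
    rejected: list[tuple[int, str]] = []
    seen: set[tuple[str, str, int]] = set()
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if header is None:
                header = parts
                for col in ALLELE_COUNT_COLUMNS:
                    if col not in header:
                        raise FormatError(
                            f"{path}: missing required column {col!r}"
                        )
                idx = {col: header.index(col) for col in ALLELE_COUNT_COLUMNS}
                continue
            if len(parts) < len(header):
                rejected.append((lineno, "too few fields"))
                continue
            line_id = parts[idx["line_id"]]
            chrom = parts[idx["chrom"]]
            try:
                pos = int(parts[idx["pos"]])
                counts = [int(parts[idx[n]]) for n in NUCLEOTIDES]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer value ({exc})")
            if pos < 1:
                rejected.append((lineno, f"pos {pos} violates 1-based coordinates"))
                continue
            if any(c < 0 for c in counts):
                rejected.append((lineno, "negative count"))
                continue
            key = (line_id, chrom, pos)
            if key in seen:
                rejected.append((lineno, f"duplicate record {key}"))
                continue
            seen.add(key)
            rows.append((line_id, chrom, pos, *counts))
    if header is None:
        raise FormatError(f"{path}: empty file, header expected")
    records = pd.DataFrame(rows, columns=list(ALLELE_COUNT_COLUMNS))
    return AlleleCountResult(records=records, rejected=rejected)


def write_allele_counts(records: pd.DataFrame, path: str | Path,
                        metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _comment_lines(metadata):
            fh.write(line + "\n")
        records.to_csv(fh, sep="\t", index=False,
                       columns=list(ALLELE_COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Continuous trait values per F1 line (the Y_i of the QTL model).

    ``values`` is lines x traits with NaN for missing measurements.
    """

    values: pd.DataFrame  # index: line ids, columns: trait names

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicated line_id(s): {list(dupes)}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicated trait name(s)")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a comma-separated phenotype sheet (first column line_id).

    Empty cells and the literal ``NA`` are missing. A duplicated line id or
    a non-numeric cell is an error with coordinates.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(row for row in fh if not row.startswith("#"))
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        traits = header[1:]
        line_ids: list[str] = []
        data: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            line_id = row[0]
            if line_id in line_ids:
                raise FormatError(f"{path}: duplicated line_id {line_id!r}")
            vals: list[float] = []
            for j, cell in enumerate(row[1:], start=1):
                cell = cell.strip()
                if cell == "" or cell == NA:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at line {lineno},"
                        f" trait {header[j]!r}"
                    )
            line_ids.append(line_id)
            data.append(vals)
    values = pd.DataFrame(data, index=line_ids, columns=traits, dtype=float)
    return PhenotypeTable(values=values)


def write_phenotypes(table: PhenotypeTable, path: str | Path,
                     metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _comment_lines(metadata):
            fh.write(line + "\n")
        out = table.values.copy()
        out.index.name = "line_id"
        out.to_csv(fh, na_rep=NA)


# ---------------------------------------------------------------------------
# marker-shaped tables (binned genotypes, dosage, state/channel matrices)
# ---------------------------------------------------------------------------

MARKER_META_COLUMNS = ("marker_id", "chrom", "start", "end")


def marker_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}_{start}_{end}"


def write_marker_table(markers: pd.DataFrame, values: pd.DataFrame,
                       path: str | Path, metadata: dict | None = None) -> None:
    """Write a marker x line table.

    ``markers`` holds marker_id, chrom, start, end (plus optional snp_count);
    ``values`` is indexed by marker_id with one column per line. Cells may be
    strings (H1/H2, state labels), numbers, or NaN (written as ``NA``).
    """
    path = Path(path)
    vals = values.reindex(markers["marker_id"])
    meta_cols = [c for c in markers.columns]
    out = pd.concat(
        [markers.reset_index(drop=True),
         vals.reset_index(drop=True)], axis=1)
    with path.open("w") as fh:
        for line in _comment_lines(metadata):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=NA)


def read_marker_table(path: str | Path,
                      value_dtype: str = "str") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a marker x line table written by :func:`write_marker_table`.

    Returns ``(markers, values)``; ``value_dtype`` is ``"str"`` for genotype
    labels or ``"float"`` for numeric matrices (dosage codes survive the
    round trip as floats with NaN for NA).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in MARKER_META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    meta_cols = [c for c in df.columns
                 if c in MARKER_META_COLUMNS or c == "snp_count"]
    markers = df[meta_cols].copy()
    markers["start"] = markers["start"].astype(int)
    markers["end"] = markers["end"].astype(int)
    if "snp_count" in markers.columns:
        markers["snp_count"] = markers["snp_count"].astype(int)
    value_cols = [c for c in df.columns if c not in meta_cols]
    values = df[value_cols].copy()
    values.index = pd.Index(markers["marker_id"], name="marker_id")
    values = values.mask(values == NA)
    if value_dtype == "float":
        values = values.astype(float)
    return markers, values


# ---------------------------------------------------------------------------
# QTL results
# ---------------------------------------------------------------------------

QTL_COLUMNS = ("trait", "channel_or_group", "chrom", "start_marker",
               "end_marker", "peak_marker", "peak_stat", "threshold",
               "variance_explained", "significance")


def write_qtl_results(results: pd.DataFrame, path: str | Path,
                      metadata: dict | None = None) -> None:
    """Write QTL calls; an empty result set produces a header-only file."""
    path = Path(path)
    out = pd.DataFrame(results, columns=list(QTL_COLUMNS))
    with path.open("w") as fh:
        for line in _comment_lines(metadata):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=NA)


def read_qtl_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in QTL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.mask(df == NA)
    for col in ("peak_stat", "threshold", "variance_explained"):
        df[col] = df[col].astype(float)
    return df
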