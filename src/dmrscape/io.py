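"""Readers and writers for the plain-text dialects the pipeline consumes.

Formats: MethylDackel-style 6-column methylation bedGraph (chrom, start,
end, %methylation, methylated count, unmethylated count), BED3/BED6,
4-column signal bedGraph, and tab-separated gene / expression / truth
tables. All files are TSV, UTF-8, LF.

Methylation fractions are always recomputed from the two count columns; the
percentage column is written for interoperability but ignored on input to
avoid rounding drift. CpGs are keyed by (chrom, pos) on one strand only:
strand merging of symmetric CpGs is assumed done upstream (the
MethylDackel default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, sort_intervals

ELEMENT_CLASSES = (
    "long_promoter",
    "core_promoter",
    "exon",
    "intron",
    "cgi",
    "enhancer",
    "repeat",
)


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


@dataclass(frozen=True)
class CpGRecord:
    """One CpG's read counts for one sample.

    ``pos`` is the 0-based position of the cytosine. ``fraction`` is
    undefined (``None``) at zero coverage.
    """

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.meth_count}, {self.unmeth_count})"
            )

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def fraction(self) -> float | None:
        cov = self.coverage
        return None if cov == 0 else self.meth_count / cov


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the TSS anchor used for promoter windows."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class ExpressionRecord:
    """Differential expression plus control-tissue FPKM for one gene."""

    gene_id: str
    fold_change: float
    p_value: float
    control_fpkm: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"{self.gene_id}: fold_change must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.gene_id}: p_value outside [0, 1]")
        if self.control_fpkm < 0:
            raise ValueError(f"{self.gene_id}: negative control_fpkm")


@dataclass(frozen=True)
class ElementSet:
    """A named class of genomic elements (exons, CGIs, ...)."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.name not in ELEMENT_CLASSES:
            raise ValueError(
                f"unknown element class {self.name!r}; expected one of {ELEMENT_CLASSES}"
            )
        object.__setattr__(self, "intervals", tuple(sort_intervals(self.intervals)))


# ---------------------------------------------------------------------------
# methylation bedGraph


def read_methylation_bedgraph(path: str | Path, sample_id: str) -> list[CpGRecord]:
    """Read a MethylDackel-dialect bedGraph into per-CpG records.

    Tolerates an optional leading ``track`` line. The position of each
    record is the start column; records are returned sorted by
    (chrom, pos).
    """
    records: list[CpGRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(CpGRecord(chrom, start, meth, unmeth, sample_id))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_methylation_bedgraph(records: Iterable[CpGRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            pct = 0 if r.coverage == 0 else round(100.0 * r.meth_count / r.coverage)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{pct}\t{r.meth_count}\t{r.unmeth_count}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; strand from column 6 when present, else ``.``."""
    out: list[GenomicInterval] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# tables


_EXPR_COLUMNS = ("gene_id", "fold_change", "p_value", "control_fpkm")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a headered TSV of per-gene differential expression."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene_id(s): {dupes}")
    return [
        ExpressionRecord(
            str(row.gene_id),
            float(row.fold_change),
            float(row.p_value),
            float(row.control_fpkm),
        )
        for row in df.itertuples()
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EXPR_COLUMNS)
        for r in records:
            writer.writerow([r.gene_id, repr(r.fold_change), repr(r.p_value), repr(r.control_fpkm)])


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a headered TSV with gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "chrom", "tss", "strand"])
        for g in genes:
            writer.writerow([g.gene_id, g.chrom, g.tss, g.strand])


# ---------------------------------------------------------------------------
# signal bedGraph (4-column)


def read_signal_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


def write_signal_bedgraph(
    runs: Sequence[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end, value in runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
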