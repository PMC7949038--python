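"""Genomic interval primitives shared by every module.

All coordinates in this package are 0-based, half-open ``[start, end)``,
BED-native. The validator here is the single authority for that contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based inclusive start and exclusive end; ``end > start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        validate_interval(self)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0


def validate_interval(iv: GenomicInterval) -> None:
    """Assert the 0-based half-open contract; raises ``ValueError`` on breach."""
    if not iv.chrom:
        raise ValueError("interval chrom must be non-empty")
    if not iv.end > iv.start:
        raise ValueError(
            f"interval end must exceed start (got [{iv.start}, {iv.end}) on {iv.chrom})"
        )
    if iv.strand not in VALID_STRANDS:
        raise ValueError(f"invalid strand {iv.strand!r}; expected one of +, -, .")
    if iv.start < 0:
        raise ValueError(f"negative start {iv.start} on {iv.chrom}")


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping ``(start, end)`` spans into a disjoint union."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_overlap_bp(target: GenomicInterval, others: Sequence[GenomicInterval]) -> int:
    """Total bp of ``target`` covered by the union of ``others``.

    Splitting any element of ``others`` into abutting pieces never changes
    the result, which is what makes the 50%-of-length overlap rule
    representation independent.
    """
    clipped = [
        (max(target.start, o.start), min(target.end, o.end))
        for o in others
        if o.chrom == target.chrom and o.start < target.end and o.end > target.start
    ]
    return sum(e - s for s, e in merge_intervals(clipped))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
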