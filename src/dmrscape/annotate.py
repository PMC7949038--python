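"""Promoter-window construction and DMR-to-element annotation.

Promoter windows are strand-aware: the long promoter spans 1500 bp
upstream to 500 bp downstream of the TSS and the core promoter 300 bp
upstream to 150 bp downstream; on the minus strand the window reflects
around the TSS. A DMR is annotated with an element class when the union of
that class's intervals covers at least ``min_overlap_frac`` (default 50%)
of the DMR's length; classes are independent, so one DMR may carry several
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .calling import DMR
from .intervals import GenomicInterval, union_overlap_bp
from .io import ElementSet, GeneModel


@dataclass(frozen=True)
class AnnotationConfig:
    long_promoter_up: int = 1500
    long_promoter_down: int = 500
    core_promoter_up: int = 300
    core_promoter_down: int = 150
    min_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        for v in (
            self.long_promoter_up,
            self.long_promoter_down,
            self.core_promoter_up,
            self.core_promoter_down,
        ):
            if v <= 0:
                raise ValueError("promoter extents must be positive")
        if not 0.0 < self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in (0, 1]")


@dataclass(frozen=True)
class AnnotatedDMR:
    dmr: DMR
    element_hits: frozenset[str]


def promoter_window(gene: GeneModel, up: int, down: int) -> GenomicInterval:
    """[tss - up, tss + down) on +, mirrored on -; clipped at 0.

    The TSS base itself sits in the downstream segment.
    """
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return GenomicInterval(gene.chrom, max(start, 0), end, gene.strand)


def make_promoters(
    genes: Sequence[GeneModel], config: AnnotationConfig = AnnotationConfig()
) -> tuple[ElementSet, ElementSet]:
    """Long and core promoter element sets for a gene list."""
    long_ivs = [
        promoter_window(g, config.long_promoter_up, config.long_promoter_down)
        for g in genes
    ]
    core_ivs = [
        promoter_window(g, config.core_promoter_up, config.core_promoter_down)
        for g in genes
    ]
    return (
        ElementSet("long_promoter", tuple(long_ivs)),
        ElementSet("core_promoter", tuple(core_ivs)),
    )


def _class_trees(element_sets: Iterable[ElementSet]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for es in element_sets:
        per_chrom = trees.setdefault(es.name, {})
        for iv in es.intervals:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_dmrs(
    dmrs: Sequence[DMR],
    element_sets: Sequence[ElementSet],
    config: AnnotationConfig = AnnotationConfig(),
) -> list[AnnotatedDMR]:
    """Assign element classes to DMRs under the 50%-of-length rule.

    The overlap per class is the union over that class's intervals, so
    abutting or overlapping element pieces never change a decision.
    """
    trees = _class_trees(element_sets)
    out = []
    for dmr in dmrs:
        hits = set()
        needed = config.min_overlap_frac * dmr.interval.length
        for name, per_chrom in trees.items():
            tree = per_chrom.get(dmr.chrom)
            if tree is None:
                continue
            touching = [h.data for h in tree.overlap(dmr.interval.start, dmr.interval.end)]
            if not touching:
                continue
            # inclusive rule: overlap >= min_overlap_frac * length
            if union_overlap_bp(dmr.interval, touching) >= needed:
                hits.add(name)
        out.append(AnnotatedDMR(dmr, frozenset(hits)))
    return out


def count_by_class(
    annotated: Sequence[AnnotatedDMR], directions: Sequence[str] = ("hypo", "hyper")
) -> pd.DataFrame:
    """Class x direction DMR counts; one DMR may increment several classes."""
    classes = sorted({name for a in annotated for name in a.element_hits})
    table = pd.DataFrame(0, index=classes, columns=list(directions), dtype=int)
    for a in annotated:
        if a.dmr.direction not in directions:
            continue
        for name in a.element_hits:
            table.loc[name, a.dmr.direction] += 1
    return table


def annotation_frame(annotated: Sequence[AnnotatedDMR]) -> pd.DataFrame:
    rows = [
        (
            a.dmr.chrom,
            a.dmr.interval.start,
            a.dmr.interval.end,
            a.dmr.direction,
            ";".join(sorted(a.element_hits)),
        )
        for a in annotated
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "elements"])
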