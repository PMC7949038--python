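"""Comparative set logic over DMR lists from multiple tumor genotypes.

Three related operations, all built on the same matching rule (two DMRs
are "the same" when their intervals share at least one base on the same
chromosome, optionally in the same direction — the bedtools-intersect
default, since no fractional criterion is part of the definition):

* a specific/overlapping partition of two tumor-vs-control comparisons;
* a transformation filter removing DMRs shared by every tumor genotype
  (changes attributable to transformation rather than the perturbed
  enzyme);
* classification of the remaining DMRs into putative catalytic-activity
  (ca) and accessory-function (af) methyltransferase targets from the
  genotype pattern: a hypomethylated region lost only when the enzyme is
  absent (ko) — but retained by the catalytically dead protein (ci) — is
  an accessory-function target, while one lost in both ko and ci needed
  the enzyme's own catalysis; hypermethylation mirrors the logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .calling import DMC, DMR

PARTITION_LABELS = ("specific_A", "specific_B", "overlapping")
MECHANISM_LABELS = ("af_target", "ca_target", "transformation", "unassigned")


@dataclass
class ComparisonResult:
    """DMRs (and optionally DMCs) of one tumor-vs-control contrast."""

    comparison_id: str
    dmrs: list[DMR]
    dmcs: list[DMC] = field(default_factory=list)


@dataclass(frozen=True)
class ClassifiedDMR:
    dmr: DMR
    source: str
    partition_label: str | None = None
    mechanism_label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.partition_label is not None and self.partition_label not in PARTITION_LABELS:
            raise ValueError(f"bad partition label {self.partition_label!r}")
        if self.mechanism_label not in MECHANISM_LABELS:
            raise ValueError(f"bad mechanism label {self.mechanism_label!r}")


def _trees(dmrs: Sequence[DMR]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, d in enumerate(dmrs):
        trees.setdefault(d.chrom, IntervalTree()).addi(
            d.interval.start, d.interval.end, i
        )
    return trees


def match_dmrs(
    set_a: Sequence[DMR], set_b: Sequence[DMR], require_same_direction: bool = True
) -> list[tuple[int, int]]:
    """Index pairs (i, j) of DMRs overlapping by >= 1 bp (half-open).

    Each DMR may participate in several pairs; "present in both" means
    participating in at least one.
    """
    trees = _trees(set_b)
    pairs = []
    for i, a in enumerate(set_a):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(a.interval.start, a.interval.end)):
            j = hit.data
            if require_same_direction and set_b[j].direction != a.direction:
                continue
            pairs.append((i, j))
    return pairs


def _matched_indices(set_a: Sequence[DMR], set_b: Sequence[DMR]) -> set[int]:
    return {i for i, _ in match_dmrs(set_a, set_b, require_same_direction=True)}


def partition_specific_overlapping(
    result_a: ComparisonResult, result_b: ComparisonResult
) -> tuple[list[ClassifiedDMR], pd.DataFrame]:
    """Label each DMR of two comparisons as specific or overlapping.

    Returns the labeled DMRs of both inputs plus a direction x label count
    table (overlapping counted on A's units).
    """
    in_b = _matched_indices(result_a.dmrs, result_b.dmrs)
    in_a = _matched_indices(result_b.dmrs, result_a.dmrs)
    labeled = [
        ClassifiedDMR(
            d,
            result_a.comparison_id,
            partition_label="overlapping" if i in in_b else "specific_A",
        )
        for i, d in enumerate(result_a.dmrs)
    ] + [
        ClassifiedDMR(
            d,
            result_b.comparison_id,
            partition_label="overlapping" if j in in_a else "specific_B",
        )
        for j, d in enumerate(result_b.dmrs)
        if j not in in_a  # overlapping counted once, on A's units
    ]
    counts = pd.DataFrame(
        0, index=["hypo", "hyper"], columns=list(PARTITION_LABELS), dtype=int
    )
    for c in labeled:
        counts.loc[c.dmr.direction, c.partition_label] += 1
    return labeled, counts


def transformation_filter(
    results: Mapping[str, ComparisonResult],
) -> tuple[dict[str, ComparisonResult], list[ClassifiedDMR]]:
    """Remove DMRs present (same direction, >= 1 bp) in ALL genotypes.

    ``results`` must hold one tumor-vs-control comparison per genotype
    (three for the canonical wt/ko/ci design). The removed DMRs are
    returned labeled ``transformation``.
    """
    genotypes = list(results)
    if len(genotypes) < 2:
        raise ValueError("transformation filter needs >= 2 genotype comparisons")
    filtered: dict[str, ComparisonResult] = {}
    removed: list[ClassifiedDMR] = []
    for g in genotypes:
        own = results[g].dmrs
        shared = set(range(len(own)))
        for other in genotypes:
            if other == g:
                continue
            shared &= _matched_indices(own, results[other].dmrs)
        keep = [d for i, d in enumerate(own) if i not in shared]
        removed.extend(
            ClassifiedDMR(own[i], results[g].comparison_id, mechanism_label="transformation")
            for i in sorted(shared)
        )
        filtered[g] = ComparisonResult(results[g].comparison_id, keep, results[g].dmcs)
    return filtered, removed


def classify_ca_af(
    filtered: Mapping[str, ComparisonResult],
    wt: str = "wt",
    ko: str = "ko",
    ci: str = "ci",
) -> tuple[list[ClassifiedDMR], pd.DataFrame]:
    """Mechanism labels from the genotype pattern, after the filter.

    Hypomethylated (on the ko list's units): in ko only -> af_target; in
    ko and ci -> ca_target; otherwise unassigned. Hypermethylated: in ci
    but not ko -> af_target (ci list's units); in wt but neither ko nor
    ci -> ca_target (wt list's units). Every DMR entering the classifier
    receives exactly one label.
    """
    for g in (wt, ko, ci):
        if g not in filtered:
            raise KeyError(f"missing genotype comparison {g!r}")
    dmrs = {g: filtered[g].dmrs for g in (wt, ko, ci)}
    matched = {
        (a, b): _matched_indices(dmrs[a], dmrs[b])
        for a in (wt, ko, ci)
        for b in (wt, ko, ci)
        if a != b
    }

    def label(genotype: str, i: int, d: DMR) -> str:
        if d.direction == "hypo":
            if genotype == ko:
                in_ci = i in matched[(ko, ci)]
                in_wt = i in matched[(ko, wt)]
                if in_ci:
                    return "ca_target"
                if not in_wt:
                    return "af_target"
            return "unassigned"
        # hyper
        if genotype == ci:
            return "unassigned" if i in matched[(ci, ko)] else "af_target"
        if genotype == wt:
            if i not in matched[(wt, ko)] and i not in matched[(wt, ci)]:
                return "ca_target"
        return "unassigned"

    labeled = [
        ClassifiedDMR(d, filtered[g].comparison_id, mechanism_label=label(g, i, d))
        for g in (wt, ko, ci)
        for i, d in enumerate(dmrs[g])
    ]
    counts = pd.DataFrame(
        0, index=["hypo", "hyper"], columns=list(MECHANISM_LABELS), dtype=int
    )
    for c in labeled:
        counts.loc[c.dmr.direction, c.mechanism_label] += 1
    return labeled, counts


def cross_reference(
    labels: Sequence[ClassifiedDMR], external: ComparisonResult
) -> pd.DataFrame:
    """Per mechanism label and direction, how many labeled DMRs recur in an
    external comparison (>= 1 bp, same direction)."""
    counts = pd.DataFrame(
        0, index=["hypo", "hyper"], columns=list(MECHANISM_LABELS), dtype=int
    )
    own = [c.dmr for c in labels]
    hit = _matched_indices(own, external.dmrs)
    for i, c in enumerate(labels):
        if i in hit:
            counts.loc[c.dmr.direction, c.mechanism_label] += 1
    return counts


def classified_frame(labels: Sequence[ClassifiedDMR]) -> pd.DataFrame:
    rows = [
        (
            c.dmr.chrom,
            c.dmr.interval.start,
            c.dmr.interval.end,
            c.dmr.direction,
            c.source,
            c.partition_label or "",
            c.mechanism_label,
        )
        for c in labels
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "source", "partition", "mechanism"],
    )
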