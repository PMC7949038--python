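"""Promoter methylation x expression integration.

Links hypomethylated promoters to genes, assigns the G1/G2/G3 expression
groups, and intersects promoter hypomethylation with overexpression
across tumor types:

* G1: promoter-hypomethylated AND upregulated (fold change >= 2, p < 0.05);
* G2: no expression change, but expressed in the control (FPKM > 0.2);
* G3: no expression change and silent in the control (FPKM < 0.2).

FPKM exactly 0.2 falls to G2 (the > in "FPKM > 0.2" is read strict and the
tie goes to the complement of the next clause). G1 requires upregulation
only: a significantly *down*-regulated gene falls through to G2/G3 by its
control FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotationConfig, promoter_window
from .calling import DMR
from .intervals import union_overlap_bp
from .io import ExpressionRecord, GeneModel

GROUPS = ("G1", "G2", "G3")


@dataclass(frozen=True)
class GeneGroupRecord:
    gene_id: str
    group: str
    promoter_dmr: DMR
    fold_change: float
    p_value: float
    control_fpkm: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def hypomethylated_promoter_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    direction: str = "hypo",
    config: AnnotationConfig = AnnotationConfig(),
    window: str = "long",
) -> dict[str, DMR]:
    """Genes whose promoter window catches >= 1 DMR of ``direction``.

    The 50%-of-DMR-length rule applies per gene promoter; when several
    DMRs hit one promoter the one with the largest |mean diff| represents
    the gene. The long promoter is the default linkage window.
    """
    if window == "long":
        up, down = config.long_promoter_up, config.long_promoter_down
    elif window == "core":
        up, down = config.core_promoter_up, config.core_promoter_down
    else:
        raise ValueError("window must be 'long' or 'core'")
    out: dict[str, DMR] = {}
    candidates = [d for d in dmrs if d.direction == direction]
    for gene in genes:
        prom = promoter_window(gene, up, down)
        best: DMR | None = None
        for d in candidates:
            if d.chrom != prom.chrom:
                continue
            ov = union_overlap_bp(d.interval, [prom])
            if ov >= config.min_overlap_frac * d.interval.length:
                if best is None or abs(d.mean_diff) > abs(best.mean_diff):
                    best = d
        if best is not None:
            out[gene.gene_id] = best
    return out


def assign_groups(
    gene_dmr_map: Mapping[str, DMR],
    expression: Sequence[ExpressionRecord],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fpkm_threshold: float = 0.2,
) -> list[GeneGroupRecord]:
    """Partition promoter-hypomethylated genes into G1/G2/G3.

    Genes absent from the expression table are skipped with a warning.
    The assignment is exhaustive and mutually exclusive over the genes
    returned.
    """
    expr = {e.gene_id: e for e in expression}
    records = []
    missing = []
    for gene_id, dmr in gene_dmr_map.items():
        e = expr.get(gene_id)
        if e is None:
            missing.append(gene_id)
            continue
        if e.fold_change >= fc_threshold and e.p_value < p_threshold:
            group = "G1"
        elif e.control_fpkm > fpkm_threshold or e.control_fpkm == fpkm_threshold:
            group = "G2"
        else:
            group = "G3"
        records.append(
            GeneGroupRecord(gene_id, group, dmr, e.fold_change, e.p_value, e.control_fpkm)
        )
    if missing:
        warnings.warn(
            f"{len(missing)} promoter-hypomethylated gene(s) missing from the "
            f"expression table were skipped: {sorted(missing)[:5]}..."
        )
    return records


def hypomethylated_overexpressed(
    per_tumor_dmr_maps: Mapping[str, Mapping[str, DMR]],
    per_tumor_expression: Mapping[str, Sequence[ExpressionRecord]],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per tumor type, genes both promoter-hypomethylated and upregulated;
    plus the list shared by every tumor type."""
    if set(per_tumor_dmr_maps) != set(per_tumor_expression):
        raise ValueError("tumor types of the two inputs must agree")
    if not per_tumor_dmr_maps:
        raise ValueError("need at least one tumor type")
    per_type: dict[str, set[str]] = {}
    for tumor, gene_map in per_tumor_dmr_maps.items():
        expr = {e.gene_id: e for e in per_tumor_expression[tumor]}
        per_type[tumor] = {
            g
            for g in gene_map
            if g in expr
            and expr[g].fold_change >= fc_threshold
            and expr[g].p_value < p_threshold
        }
    shared = set.intersection(*per_type.values())
    return per_type, shared


def group_frame(records: Sequence[GeneGroupRecord]) -> pd.DataFrame:
    rows = [
        (
            r.gene_id,
            r.group,
            r.promoter_dmr.chrom,
            r.promoter_dmr.interval.start,
            r.promoter_dmr.interval.end,
            r.promoter_dmr.mean_diff,
            r.promoter_dmr.p_mwu,
            r.fold_change,
            r.p_value,
            r.control_fpkm,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "group", "chrom", "start", "end",
            "mean_diff", "p_mwu", "fold_change", "p_value", "control_fpkm",
        ],
    )
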