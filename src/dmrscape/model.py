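"""Model/Results front end for differential methylation between two groups.

``DifferentialMethylation`` is constructed from a coverage-filtered
``MethylMatrix`` (or directly from per-sample CpG records) together with
the two sample groups; ``fit()`` runs DMC calling and DMR chaining and
returns a ``DifferentialMethylationResults`` carrying the calls, the
thresholds used, and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import (
    DMC,
    DMR,
    CallerConfig,
    MethylMatrix,
    build_matrix,
    call_dmcs,
    call_dmrs,
    dmr_frame,
    group_means,
    write_dmr_bed,
)
from .io import CpGRecord
from .reporting import fraction_pct


class DifferentialMethylation:
    """Two-group differential methylation model over a CpG x sample matrix.

    Parameters
    ----------
    matrix : MethylMatrix
        Methylation fractions after the all-sample coverage filter.
    group_a, group_b : sequence of str
        Sample ids of the reference (A, e.g. normal tissue) and test
        (B, e.g. tumor) groups. Differences are B - A, so ``hypo`` means
        loss of methylation in B.
    config : CallerConfig, optional
        Thresholds of the DMC/DMR definition.
    """

    def __init__(
        self,
        matrix: MethylMatrix,
        group_a: Sequence[str],
        group_b: Sequence[str],
        config: CallerConfig | None = None,
    ) -> None:
        self.matrix = matrix
        self.group_a = list(group_a)
        self.group_b = list(group_b)
        self.config = config or CallerConfig()
        # validates group membership/disjointness eagerly
        group_means(matrix, self.group_a, self.group_b)

    @classmethod
    def from_samples(
        cls,
        samples_a: Mapping[str, Iterable[CpGRecord]],
        samples_b: Mapping[str, Iterable[CpGRecord]],
        config: CallerConfig | None = None,
    ) -> "DifferentialMethylation":
        """Build the coverage-filtered matrix from raw per-sample records."""
        config = config or CallerConfig()
        overlap = set(samples_a) & set(samples_b)
        if overlap:
            raise ValueError(f"sample ids in both groups: {sorted(overlap)}")
        merged = {**dict(samples_a), **dict(samples_b)}
        matrix = build_matrix(merged, config)
        return cls(matrix, list(samples_a), list(samples_b), config)

    def fit(self) -> "DifferentialMethylationResults":
        dmcs = call_dmcs(self.matrix, self.group_a, self.group_b, self.config)
        dmrs = call_dmrs(dmcs, self.matrix, self.group_a, self.group_b, self.config)
        return DifferentialMethylationResults(self, dmcs, dmrs)


@dataclass
class DifferentialMethylationResults:
    """DMC/DMR calls plus the matrix and thresholds that produced them."""

    model: DifferentialMethylation
    dmcs: list[DMC]
    dmrs: list[DMR]

    @property
    def config(self) -> CallerConfig:
        return self.model.config

    def dmc_counts(self) -> dict[str, int]:
        return {
            "hypo": sum(1 for d in self.dmcs if d.direction == "hypo"),
            "hyper": sum(1 for d in self.dmcs if d.direction == "hyper"),
        }

    def dmr_counts(self) -> dict[str, int]:
        return {
            "hypo": sum(1 for d in self.dmrs if d.direction == "hypo"),
            "hyper": sum(1 for d in self.dmrs if d.direction == "hyper"),
        }

    def dmc_rate_pct(self, direction: str, ndigits: int | None = None) -> float:
        """Share of analyzable CpGs called as DMCs in one direction, in %."""
        return fraction_pct(
            self.dmc_counts()[direction], self.model.matrix.n_cpgs, ndigits
        )

    def dmr_frame(self) -> pd.DataFrame:
        return dmr_frame(self.dmrs)

    def to_bed(self, path) -> None:
        write_dmr_bed(self.dmrs, path)

    def summary(self) -> str:
        cfg = self.config
        n = self.model.matrix.n_cpgs
        dmc = self.dmc_counts()
        dmr = self.dmr_counts()
        lines = [
            "Differential methylation results (group B vs group A)",
            "=" * 56,
            f"analyzable CpGs (>= {cfg.min_coverage}x in all samples): {n}",
            f"group A: {', '.join(self.model.group_a)}",
            f"group B: {', '.join(self.model.group_b)}",
            (
                f"DMC threshold |diff| >= {cfg.delta_threshold:.2f}; "
                f"DMR: >= {cfg.min_cpgs} DMCs, gap <= {cfg.max_gap} bp, "
                f"p(MWU) < {cfg.p_threshold:.2f}"
            ),
            (
                f"hypo DMCs:  {dmc['hypo']:>8d} "
                f"({self.dmc_rate_pct('hypo', 2)}% of CpGs)"
            ),
            (
                f"hyper DMCs: {dmc['hyper']:>8d} "
                f"({self.dmc_rate_pct('hyper', 2)}% of CpGs)"
            ),
            f"hypo DMRs:  {dmr['hypo']:>8d}",
            f"hyper DMRs: {dmr['hyper']:>8d}",
        ]
        return "\n".join(lines)
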