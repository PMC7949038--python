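"""DMC and DMR calling from per-CpG bisulfite counts.

The contract implemented here is the standard Metilene-style regional
definition: a CpG is a differentially methylated cytosine (DMC) when the
group-mean methylation difference reaches ``delta_threshold`` (default 30
percentage points, inclusive); a differentially methylated region (DMR) is
a maximal chain of at least ``min_cpgs`` same-direction DMCs whose
consecutive members are at most ``max_gap`` bp apart, kept only when the
regional two-sided Mann-Whitney U p-value is below ``p_threshold``.

Only CpGs covered at least ``min_coverage``-fold in EVERY sample enter the
analysis. Group B is the tumor group by convention, so a negative
difference (B - A) means hypomethylation in the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import CpGRecord
from .stats import mwu_test


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the DMC/DMR definition.

    mwu_values selects the values handed to the regional test:
    ``"pooled"`` (default) pools the per-sample methylation fractions of
    the region's member CpGs, so group A contributes n_cpgs * n_samples_a
    values; ``"group_means"`` uses the per-CpG group-mean vectors instead
    (n_cpgs values per group). The pooled form is the default because the
    group-mean form cannot reach p < 0.05 for a 3-CpG region (the exact
    two-sided 3-vs-3 p-value is at least 0.1), which would contradict the
    stated minimum region size.
    """

    min_coverage: int = 5
    delta_threshold: float = 0.30
    max_gap: int = 50
    min_cpgs: int = 3
    p_threshold: float = 0.05
    strict_consecutive: bool = False
    mwu_values: str = "pooled"

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.max_gap < 0 or self.min_cpgs <= 0:
            raise ValueError("caller thresholds must be positive")
        if not 0.0 < self.delta_threshold <= 1.0:
            raise ValueError("delta_threshold must be in (0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.mwu_values not in ("pooled", "group_means"):
            raise ValueError("mwu_values must be 'pooled' or 'group_means'")


@dataclass(frozen=True)
class DMC:
    """A differentially methylated cytosine (group B minus group A)."""

    chrom: str
    pos: int
    mean_a: float
    mean_b: float
    diff: float
    direction: str  # "hypo" (diff < 0) or "hyper"


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region spanning its member CpGs."""

    interval: GenomicInterval
    n_cpgs: int
    direction: str
    mean_diff: float
    p_mwu: float
    member_pos: tuple[int, ...] = field(default=())

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class NoAnalyzableCpGsError(ValueError):
    """Raised when the all-sample coverage filter leaves nothing to test."""


@dataclass
class MethylMatrix:
    """CpGs x samples methylation fractions after the all-sample filter.

    Rows are (chrom, pos) sorted; every retained CpG is covered at least
    ``min_coverage``-fold in every sample.
    """

    chroms: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    fractions: np.ndarray  # (n_cpgs, n_samples) in [0, 1]
    coverages: np.ndarray  # (n_cpgs, n_samples) ints

    def __post_init__(self) -> None:
        if self.fractions.shape != self.coverages.shape:
            raise ValueError("fractions and coverages must share a shape")
        if self.fractions.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        if self.fractions.size and (
            self.fractions.min() < 0.0 or self.fractions.max() > 1.0
        ):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    def columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.sample_ids.index(s) for s in sample_ids])
        except ValueError as exc:
            raise KeyError(f"unknown sample id among {list(sample_ids)}") from exc

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=self.sample_ids)
        df.insert(0, "chrom", self.chroms)
        df.insert(1, "pos", self.positions)
        return df


def _records_to_frame(records: Iterable[CpGRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.meth_count, r.coverage) for r in records]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "cov"])
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) within one sample")
    return df.set_index(["chrom", "pos"])


def build_matrix(
    samples: Mapping[str, Iterable[CpGRecord]], config: CallerConfig = CallerConfig()
) -> MethylMatrix:
    """Intersect samples on CpGs covered >= min_coverage in all of them."""
    if len(samples) < 2:
        raise ValueError("need at least two samples to build a matrix")
    sample_ids = list(samples)
    frames = []
    for sid in sample_ids:
        df = _records_to_frame(samples[sid])
        df = df[df["cov"] >= config.min_coverage]
        frames.append(df.rename(columns={"meth": f"meth_{sid}", "cov": f"cov_{sid}"}))
    joined = pd.concat(frames, axis=1, join="inner").sort_index()
    if joined.empty:
        raise NoAnalyzableCpGsError(
            f"no CpGs covered >= {config.min_coverage}x in all {len(sample_ids)} samples"
        )
    cov = joined[[f"cov_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    meth = joined[[f"meth_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    idx = joined.index
    return MethylMatrix(
        chroms=np.asarray(idx.get_level_values(0), dtype=object),
        positions=np.asarray(idx.get_level_values(1), dtype=np.int64),
        sample_ids=sample_ids,
        fractions=meth / cov,
        coverages=cov,
    )


def group_means(
    matrix: MethylMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG unweighted means of per-sample fractions within each group."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    cols_a = matrix.columns(group_a)
    cols_b = matrix.columns(group_b)
    return (
        matrix.fractions[:, cols_a].mean(axis=1),
        matrix.fractions[:, cols_b].mean(axis=1),
    )


def call_dmcs(
    matrix: MethylMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: CallerConfig = CallerConfig(),
) -> list[DMC]:
    """CpGs whose |group-mean difference| reaches the threshold (inclusive)."""
    mean_a, mean_b = group_means(matrix, group_a, group_b)
    diff = mean_b - mean_a
    # tolerance guards the inclusive ">= 30%" boundary against float error
    keep = np.abs(diff) >= config.delta_threshold - 1e-12
    out = []
    for i in np.flatnonzero(keep):
        d = float(diff[i])
        out.append(
            DMC(
                chrom=str(matrix.chroms[i]),
                pos=int(matrix.positions[i]),
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                diff=d,
                direction="hypo" if d < 0 else "hyper",
            )
        )
    return out


def _chain_dmcs(dmcs: Sequence[DMC], matrix: MethylMatrix, config: CallerConfig):
    """Greedy left-to-right chaining of same-direction DMCs within max_gap.

    By default an intervening retained non-DMC CpG does not break a chain
    (only distance and direction do); with ``strict_consecutive`` any
    retained CpG between two successive DMC members breaks it.
    """
    retained = {}
    if config.strict_consecutive:
        for i in range(matrix.n_cpgs):
            retained.setdefault(str(matrix.chroms[i]), []).append(int(matrix.positions[i]))
    chains: list[list[DMC]] = []
    current: list[DMC] = []
    for dmc in sorted(dmcs, key=lambda d: (d.chrom, d.pos)):
        if current:
            prev = current[-1]
            ok = (
                dmc.chrom == prev.chrom
                and dmc.direction == prev.direction
                and dmc.pos - prev.pos <= config.max_gap
            )
            if ok and config.strict_consecutive:
                between = [
                    p for p in retained.get(dmc.chrom, []) if prev.pos < p < dmc.pos
                ]
                ok = not between
            if not ok:
                chains.append(current)
                current = []
        current.append(dmc)
    if current:
        chains.append(current)
    return chains


def call_dmrs(
    dmcs: Sequence[DMC],
    matrix: MethylMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: CallerConfig = CallerConfig(),
) -> list[DMR]:
    """Chain DMCs into candidate regions and keep the MWU-significant ones."""
    cols_a = matrix.columns(group_a)
    cols_b = matrix.columns(group_b)
    row_of = {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(matrix.chroms, matrix.positions))
    }
    out: list[DMR] = []
    for chain in _chain_dmcs(dmcs, matrix, config):
        if len(chain) < config.min_cpgs:
            continue
        rows = np.array([row_of[(d.chrom, d.pos)] for d in chain])
        if config.mwu_values == "pooled":
            values_a = matrix.fractions[np.ix_(rows, cols_a)].ravel()
            values_b = matrix.fractions[np.ix_(rows, cols_b)].ravel()
        else:
            values_a = matrix.fractions[np.ix_(rows, cols_a)].mean(axis=1)
            values_b = matrix.fractions[np.ix_(rows, cols_b)].mean(axis=1)
        p = mwu_test(values_a, values_b)
        if not p < config.p_threshold:
            continue
        out.append(
            DMR(
                interval=GenomicInterval(chain[0].chrom, chain[0].pos, chain[-1].pos + 1),
                n_cpgs=len(chain),
                direction=chain[0].direction,
                mean_diff=float(np.mean([d.diff for d in chain])),
                p_mwu=p,
                member_pos=tuple(d.pos for d in chain),
            )
        )
    return out


def validate_dmr(dmr: DMR, dmcs_by_pos: Mapping[tuple[str, int], DMC], config: CallerConfig) -> None:
    """Assert every stored DMR invariant; raises ``AssertionError`` on breach."""
    assert dmr.n_cpgs >= config.min_cpgs
    assert dmr.n_cpgs == len(dmr.member_pos)
    assert dmr.p_mwu < config.p_threshold
    assert dmr.interval.start == dmr.member_pos[0]
    assert dmr.interval.end == dmr.member_pos[-1] + 1
    for prev, nxt in zip(dmr.member_pos, dmr.member_pos[1:]):
        assert 0 < nxt - prev <= config.max_gap
    for pos in dmr.member_pos:
        member = dmcs_by_pos[(dmr.chrom, pos)]
        assert member.direction == dmr.direction
        assert abs(member.diff) >= config.delta_threshold - 1e-12


def dmr_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """DMRs as a BED6+-shaped DataFrame (extra columns n_cpgs, mean_diff, p_mwu, direction)."""
    rows = [
        (
            d.chrom,
            d.interval.start,
            d.interval.end,
            f"dmr_{i}",
            int(round(1000 * abs(d.mean_diff))),
            ".",
            d.n_cpgs,
            d.mean_diff,
            d.p_mwu,
            d.direction,
        )
        for i, d in enumerate(dmrs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_cpgs", "mean_diff", "p_mwu", "direction",
        ],
    )


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    dmr_frame(dmrs).to_csv(path, sep="\t", header=False, index=False)


def read_dmr_bed(path) -> list[DMR]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_cpgs", "mean_diff", "p_mwu", "direction",
        ],
    )
    return [
        DMR(
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            n_cpgs=int(r.n_cpgs),
            direction=str(r.direction),
            mean_diff=float(r.mean_diff),
            p_mwu=float(r.p_mwu),
        )
        for r in df.itertuples()
    ]
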