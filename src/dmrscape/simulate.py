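"""Synthetic multi-genotype methylome generator with a planted truth table.

The generator emulates the statistical structure of a multi-sample WGBS
study of tumor genotypes against a normal-tissue control: CpG positions
with roughly geometric spacing, a bimodal (mostly-methylated /
mostly-unmethylated) beta-mixture baseline shared by all genotypes, and
planted differentially methylated regions of known width, shift and
genotype pattern. Observed counts follow a Poisson coverage / binomial
methylated-count read model per sample, with replicate-specific RNG
substreams so every sample is reproducible in isolation.

Planted regions are CpG-dense (island-like spacing of ~12-20 bp) and draw
their baseline from the mixture component that can actually absorb the
shift: regions losing methylation start from the methylated component,
regions gaining it from the unmethylated one. Matched expression tables
and per-base signal tracks for the downstream integration and profiling
stages are generated from the same truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import CpGRecord, ExpressionRecord, GeneModel

CATEGORIES = (
    "af_target",
    "ca_target",
    "transformation",
    "specific_A",
    "specific_B",
    "none",
)

EXPRESSION_GROUPS = ("G1", "G2", "G3")


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture for genome-wide baseline methylation.

    Defaults mimic the bimodality of vertebrate methylomes: 70% of CpGs
    highly methylated (Beta(9, 1), mean 0.9), 30% lowly methylated
    (Beta(1, 9), mean 0.1).
    """

    weight_high: float = 0.70
    high: tuple[float, float] = (9.0, 1.0)
    low: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pick_high = rng.random(n) < self.weight_high
        out = np.where(
            pick_high,
            rng.beta(*self.high, size=n),
            rng.beta(*self.low, size=n),
        )
        return out

    def sample_component(self, rng: np.random.Generator, n: int, which: str) -> np.ndarray:
        a, b = self.high if which == "high" else self.low
        return rng.beta(a, b, size=n)


@dataclass(frozen=True)
class PlantedRegion:
    """A ground-truth differential region.

    ``affected_genotypes`` lists the tumor genotypes whose true methylation
    is shifted by ``delta`` (tumor minus control) over the region's CpGs.
    ``category`` is a truth label for recovery bookkeeping; ``gene_id`` and
    ``expression_group`` tag promoter-overlapping regions for the
    expression-integration stages.
    """

    interval: GenomicInterval
    n_cpgs: int
    delta: float
    category: str
    affected_genotypes: frozenset[str] = frozenset()
    gene_id: str | None = None
    expression_group: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.n_cpgs < 3:
            raise ValueError("planted regions need >= 3 CpGs to be callable")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [-1, 1]")
        if self.expression_group is not None and self.expression_group not in EXPRESSION_GROUPS:
            raise ValueError(f"unknown expression group {self.expression_group!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_cpgs: int = 50_000
    mean_spacing_bp: float = 100.0
    coverage_lambda: float = 30.0
    baseline: BetaMixture = BetaMixture()
    planted_regions: tuple[PlantedRegion, ...] = ()
    genotypes: tuple[tuple[str, int], ...] = (("control", 2), ("tumor", 2))
    chrom: str = "chrS1"
    region_cpg_spacing: tuple[int, int] = (12, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 10:
            raise ValueError("n_cpgs must be >= 10")
        if self.coverage_lambda <= 0 or self.mean_spacing_bp <= 0:
            raise ValueError("coverage_lambda and mean_spacing_bp must be positive")
        names = [g for g, _ in self.genotypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genotype ids")
        known = set(names)
        for r in self.planted_regions:
            unknown = r.affected_genotypes - known
            if unknown:
                raise ValueError(f"region affects unknown genotype(s) {sorted(unknown)}")

    @property
    def genotype_ids(self) -> list[str]:
        return [g for g, _ in self.genotypes]

    def replicates(self, genotype: str) -> int:
        for g, n in self.genotypes:
            if g == genotype:
                return n
        raise KeyError(f"unknown genotype {genotype!r}")


@dataclass
class SyntheticTruth:
    """The noise-free study: positions, per-genotype true fractions, regions."""

    config: SimulationConfig
    positions: np.ndarray
    baseline: np.ndarray
    fractions: dict[str, np.ndarray]
    region_index: np.ndarray  # per-CpG index into config.planted_regions, -1 outside

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def truth_table(self) -> pd.DataFrame:
        rows = [
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                r.n_cpgs,
                r.delta,
                r.category,
                ",".join(sorted(r.affected_genotypes)),
                r.gene_id or "",
                r.expression_group or "",
            )
            for r in self.config.planted_regions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "n_cpgs", "delta", "category",
                "affected_genotypes", "gene_id", "expression_group",
            ],
        )


def _check_no_overlap(regions: Sequence[PlantedRegion]) -> None:
    ordered = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise ValueError(
                f"planted regions overlap: {a.interval} and {b.interval}"
            )


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Lay out CpGs and the per-genotype true methylation surface.

    Deterministic for a fixed config seed. Background CpGs take geometric
    spacing of mean ``mean_spacing_bp``; each planted region places its own
    ``n_cpgs`` at dense uniform spacing inside its interval. Outside
    planted regions all genotypes share the baseline exactly.
    """
    _check_no_overlap(config.planted_regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    regions = sorted(config.planted_regions, key=lambda r: r.interval.start)
    region_order = {id(r): i for i, r in enumerate(config.planted_regions)}

    n_planted = sum(r.n_cpgs for r in regions)
    n_background = max(config.n_cpgs - n_planted, 0)

    gaps = rng.geometric(1.0 / config.mean_spacing_bp, size=n_background)
    bg_pos = np.cumsum(gaps) + 1000  # leave headroom at the chromosome start
    # drop background CpGs that fall inside a planted interval
    keep = np.ones(len(bg_pos), dtype=bool)
    for r in regions:
        keep &= ~((bg_pos >= r.interval.start) & (bg_pos < r.interval.end))
    bg_pos = bg_pos[keep]

    positions = [bg_pos]
    owners = [np.full(len(bg_pos), -1, dtype=np.int64)]
    for r in regions:
        lo, hi = config.region_cpg_spacing
        spacing = int(rng.integers(lo, hi + 1))
        start = r.interval.start + 1
        pos = start + spacing * np.arange(r.n_cpgs)
        if pos[-1] >= r.interval.end:
            # compress to fit narrow intervals
            pos = np.linspace(r.interval.start + 1, r.interval.end - 1, r.n_cpgs).astype(
                np.int64
            )
        positions.append(pos.astype(np.int64))
        owners.append(np.full(r.n_cpgs, region_order[id(r)], dtype=np.int64))

    pos_all = np.concatenate(positions)
    owner_all = np.concatenate(owners)
    order = np.argsort(pos_all, kind="mergesort")
    pos_all, owner_all = pos_all[order], owner_all[order]
    if len(np.unique(pos_all)) != len(pos_all):  # collisions are harmless to nudge
        _, first = np.unique(pos_all, return_index=True)
        mask = np.zeros(len(pos_all), dtype=bool)
        mask[first] = True
        pos_all, owner_all = pos_all[mask], owner_all[mask]

    baseline = config.baseline.sample(rng, len(pos_all))
    for i, r in enumerate(config.planted_regions):
        members = owner_all == i
        if not members.any():
            continue
        component = "high" if r.delta < 0 else "low"
        if r.delta == 0:
            continue
        baseline[members] = config.baseline.sample_component(
            rng, int(members.sum()), component
        )

    fractions: dict[str, np.ndarray] = {}
    for genotype in config.genotype_ids:
        surface = baseline.copy()
        for i, r in enumerate(config.planted_regions):
            if genotype in r.affected_genotypes and r.delta != 0.0:
                members = owner_all == i
                surface[members] = np.clip(surface[members] + r.delta, 0.0, 1.0)
        fractions[genotype] = surface

    return SyntheticTruth(
        config=config,
        positions=pos_all,
        baseline=baseline,
        fractions=fractions,
        region_index=owner_all,
    )


def simulate_sample(
    truth: SyntheticTruth, genotype: str, replicate: int
) -> list[CpGRecord]:
    """Draw one sample's read counts from the truth surface.

    Coverage ~ Poisson(coverage_lambda); methylated count ~
    Binomial(coverage, true fraction). The RNG substream is keyed by
    (seed, genotype index, replicate), so replicates differ but each is
    reproducible independently of simulation order.
    """
    config = truth.config
    if genotype not in truth.fractions:
        raise KeyError(f"unknown genotype {genotype!r}")
    gi = config.genotype_ids.index(genotype)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, gi, replicate]))
    n = len(truth.positions)
    coverage = rng.poisson(config.coverage_lambda, size=n)
    meth = rng.binomial(coverage, truth.fractions[genotype])
    sample_id = f"{genotype}_r{replicate}"
    return [
        CpGRecord(truth.chrom, int(p), int(m), int(c - m), sample_id)
        for p, m, c in zip(truth.positions, meth, coverage)
    ]


def simulate_study(truth: SyntheticTruth) -> dict[str, dict[str, list[CpGRecord]]]:
    """All genotypes x replicates; keyed [genotype][sample_id]."""
    out: dict[str, dict[str, list[CpGRecord]]] = {}
    for genotype, n_rep in truth.config.genotypes:
        out[genotype] = {
            f"{genotype}_r{rep}": simulate_sample(truth, genotype, rep)
            for rep in range(n_rep)
        }
    return out


# ---------------------------------------------------------------------------
# genes and expression


def truth_genes(truth: SyntheticTruth, n_null_genes: int = 20) -> list[GeneModel]:
    """One gene per gene-tagged region (TSS just downstream, so the long
    promoter window covers the region) plus unaffected filler genes."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, 303]))
    genes = []
    for r in truth.config.planted_regions:
        if r.gene_id is None:
            continue
        tss = r.interval.end + 200
        genes.append(GeneModel(r.gene_id, truth.chrom, tss, "+"))
    span = int(truth.positions[-1]) if len(truth.positions) else 10_000
    for k in range(n_null_genes):
        tss = int(rng.integers(2000, span + 2000))
        genes.append(GeneModel(f"null_gene_{k}", truth.chrom, tss, "+"))
    return genes


def simulate_expression(
    truth: SyntheticTruth, n_null_genes: int = 20
) -> list[ExpressionRecord]:
    """Expression records consistent with each gene's designated group.

    G1: fold change >= 2 and p < 0.05 (construction guarantees it);
    G2: fold change ~ 1, control FPKM > 0.2;
    G3: fold change ~ 1, control FPKM < 0.2. FPKM noise is lognormal.
    Null genes behave like G2.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, 304]))
    records = []
    for gene in truth_genes(truth, n_null_genes=n_null_genes):
        group = None
        for r in truth.config.planted_regions:
            if r.gene_id == gene.gene_id:
                group = r.expression_group
                break
        if group == "G1":
            fc = float(2.0 + rng.lognormal(0.5, 0.5))
            p = float(rng.uniform(1e-6, 0.04))
            fpkm = float(rng.lognormal(1.0, 0.8))
        elif group == "G3":
            fc = float(np.clip(rng.lognormal(0.0, 0.15), 0.5, 1.9))
            p = float(rng.uniform(0.1, 0.95))
            fpkm = float(rng.uniform(0.001, 0.15))
        else:  # G2 and null genes
            fc = float(np.clip(rng.lognormal(0.0, 0.15), 0.5, 1.9))
            p = float(rng.uniform(0.1, 0.95))
            fpkm = float(0.25 + rng.lognormal(0.5, 0.8))
        records.append(ExpressionRecord(gene.gene_id, fc, p, fpkm))
    return records


_NONPROMOTER_CLASSES = ("exon", "intron", "cgi", "enhancer", "repeat")


def simulate_elements(
    truth: SyntheticTruth, n_background_per_class: int = 30
) -> list["ElementSet"]:
    """Genomic-element sets for the annotation stage.

    Each planted region is fully covered by one non-promoter element class
    (assigned round-robin) so element hits are predictable; background
    intervals of each class are scattered along the chromosome.
    """
    from .io import ElementSet  # local import avoids a cycle at module load

    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, 306]))
    span = int(truth.positions[-1]) if len(truth.positions) else 10_000
    members: dict[str, list[GenomicInterval]] = {c: [] for c in _NONPROMOTER_CLASSES}
    for i, r in enumerate(truth.config.planted_regions):
        cls = _NONPROMOTER_CLASSES[i % len(_NONPROMOTER_CLASSES)]
        members[cls].append(
            GenomicInterval(truth.chrom, max(r.interval.start - 20, 0), r.interval.end + 20)
        )
    for cls in _NONPROMOTER_CLASSES:
        for _ in range(n_background_per_class):
            start = int(rng.integers(0, span))
            members[cls].append(
                GenomicInterval(truth.chrom, start, start + int(rng.integers(100, 600)))
            )
    return [ElementSet(cls, tuple(ivs)) for cls, ivs in members.items()]


# ---------------------------------------------------------------------------
# signal tracks


def simulate_signal_track(
    truth: SyntheticTruth,
    enrichment: Mapping[str, float],
    background_mean: float = 1.0,
    noise_sd: float = 0.05,
    ramp_bp: int = 50,
) -> np.ndarray:
    """Per-base signal: noisy background times a region-enrichment envelope.

    ``enrichment`` maps truth categories to multiplicative levels (e.g.
    ``{"af_target": 5.0}``); the envelope is flat at the multiplier across
    each region with linear ramps of ``ramp_bp`` outside it, so the mean
    in-region signal is ``multiplier x background_mean``. Deterministic for
    the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, 405]))
    length = int(truth.positions[-1]) + 2 * ramp_bp + 1000 if len(truth.positions) else 10_000
    envelope = np.ones(length)
    for r in truth.config.planted_regions:
        mult = float(enrichment.get(r.category, 1.0))
        if mult == 1.0:
            continue
        s, e = r.interval.start, min(r.interval.end, length)
        envelope[s:e] = np.maximum(envelope[s:e], mult)
        up = np.linspace(1.0, mult, ramp_bp, endpoint=False)
        lo = max(s - ramp_bp, 0)
        envelope[lo:s] = np.maximum(envelope[lo:s], up[ramp_bp - (s - lo):])
        down = np.linspace(mult, 1.0, ramp_bp + 1)[1:]
        hi = min(e + ramp_bp, length)
        envelope[e:hi] = np.maximum(envelope[e:hi], down[: hi - e])
    noise = np.abs(rng.normal(background_mean, noise_sd, size=length))
    return noise * envelope


def signal_track_runs(track: np.ndarray, chrom: str) -> list[tuple[str, int, int, float]]:
    """Compress a dense per-base track into bedGraph runs of equal value."""
    if len(track) == 0:
        return []
    change = np.flatnonzero(np.diff(track)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(track)]])
    return [(chrom, int(s), int(e), float(track[s])) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# canonical study layouts


#: tumor-vs-control shift used throughout the default study
DEFAULT_DELTA = 0.40

_DEFAULT_GENOTYPES = (("control", 2), ("wt", 2), ("ko", 2), ("ci", 2))

# category -> (delta sign, affected tumor genotypes, count at default scale)
_DEFAULT_LAYOUT = (
    ("transformation", -1, ("wt", "ko", "ci"), 10),
    ("af_target", -1, ("ko",), 10),
    ("ca_target", -1, ("ko", "ci"), 10),
    ("af_target", +1, ("ci",), 8),
    ("ca_target", +1, ("wt",), 8),
    ("none", 0, (), 8),
)

_GENE_GROUP_COUNTS = {"G1": 5, "G2": 5, "G3": 5}


def default_study_config(
    seed: int = 0,
    scale: str = "default",
    delta: float = DEFAULT_DELTA,
    coverage_lambda: float = 30.0,
    region_n_cpgs: int = 5,
) -> SimulationConfig:
    """The canonical synthetic study: a control plus three tumor genotypes.

    Genotype semantics mirror a catalytic-inactive (ci) / full-knockout
    (ko) / wild-type-enzyme (wt) tumor series against a healthy control:
    regions lost only in ko are accessory-function targets, regions lost in
    both ko and ci are catalytic targets, regions shifted in every tumor
    are transformation effects, and hypermethylation mirrors the logic.

    ``scale="tiny"`` gives ~200 background CpGs and 3 planted regions for
    fast tests; ``"default"`` gives ~50,000 CpGs and ~69 regions.
    """
    if scale == "tiny":
        layout = (
            ("af_target", -1, ("ko",), 1),
            ("transformation", -1, ("wt", "ko", "ci"), 1),
            ("af_target", +1, ("ci",), 1),
        )
        n_cpgs, gene_groups = 200, {}
    elif scale == "default":
        layout, n_cpgs, gene_groups = _DEFAULT_LAYOUT, 50_000, _GENE_GROUP_COUNTS
    else:
        raise ValueError("scale must be 'tiny' or 'default'")

    regions: list[PlantedRegion] = []
    cursor = 5_000
    # regions spaced far beyond 2x max_gap so chains cannot bridge truths
    stride = 2_000
    width = 120
    counter = 0
    for category, sign, affected, count in layout:
        for _ in range(count):
            regions.append(
                PlantedRegion(
                    interval=GenomicInterval("chrS1", cursor, cursor + width),
                    n_cpgs=region_n_cpgs,
                    delta=sign * delta,
                    category=category,
                    affected_genotypes=frozenset(affected),
                )
            )
            counter += 1
            cursor += stride
    for group, count in gene_groups.items():
        for k in range(count):
            regions.append(
                PlantedRegion(
                    interval=GenomicInterval("chrS1", cursor, cursor + width),
                    n_cpgs=region_n_cpgs,
                    delta=-delta,
                    category="af_target",
                    affected_genotypes=frozenset({"ko"}),
                    gene_id=f"{group.lower()}_gene_{k}",
                    expression_group=group,
                )
            )
            cursor += stride
    return SimulationConfig(
        n_cpgs=n_cpgs,
        coverage_lambda=coverage_lambda,
        planted_regions=tuple(regions),
        genotypes=_DEFAULT_GENOTYPES,
        seed=seed,
    )


def expected_partition_label(region: PlantedRegion, genotype_a: str, genotype_b: str) -> str | None:
    """Truth label for the two-comparison specific/overlapping partition."""
    in_a = genotype_a in region.affected_genotypes
    in_b = genotype_b in region.affected_genotypes
    if in_a and in_b:
        return "overlapping"
    if in_a:
        return "specific_A"
    if in_b:
        return "specific_B"
    return None
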