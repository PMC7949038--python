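"""End-to-end orchestration: simulate -> call -> annotate -> classify ->
integrate -> profile, with a JSON manifest of outputs and parameters.

One global seed is fanned out to per-stage substreams inside the
generator, so a manifest re-run reproduces every output byte for byte.
The per-stage counts logged in the manifest (CpGs retained, DMCs, DMRs
per direction, labels per class) are the pipeline's primary readout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import AnnotationConfig, annotate_dmrs, count_by_class, make_promoters
from .calling import CallerConfig
from .integrate import (
    assign_groups,
    group_frame,
    hypomethylated_promoter_genes,
)
from .io import (
    write_bed,
    write_expression_table,
    write_gene_table,
    write_methylation_bedgraph,
    write_signal_bedgraph,
)
from .model import DifferentialMethylation
from .profiles import SignalTrack, compare_profiles, scaled_region_profile
from .setlogic import (
    ComparisonResult,
    classified_frame,
    classify_ca_af,
    transformation_filter,
)
from .simulate import (
    default_study_config,
    generate_truth,
    signal_track_runs,
    simulate_elements,
    simulate_expression,
    simulate_signal_track,
    simulate_study,
    truth_genes,
)

_CALLER_KEYS = {f.name for f in dataclasses.fields(CallerConfig)}
_ANNOT_KEYS = {f.name for f in dataclasses.fields(AnnotationConfig)}
_SIM_KEYS = {"scale", "delta", "coverage_lambda", "region_n_cpgs"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "dmrscape_out"
    scale: str = "default"
    delta: float = 0.40
    coverage_lambda: float = 30.0
    region_n_cpgs: int = 5
    caller: CallerConfig = field(default_factory=CallerConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        caller = CallerConfig(**_take(raw.pop("caller", {}), _CALLER_KEYS, "caller"))
        annotation = AnnotationConfig(
            **_take(raw.pop("annotation", {}), _ANNOT_KEYS, "annotation")
        )
        top_keys = {"seed", "outdir"} | _SIM_KEYS
        unknown = set(raw) - top_keys
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(caller=caller, annotation=annotation, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _take(section: dict, allowed: set[str], name: str) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {name} config key(s): {sorted(unknown)}")
    return section


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(manifest, out)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    study_cfg = default_study_config(
        seed=config.seed,
        scale=config.scale,
        delta=config.delta,
        coverage_lambda=config.coverage_lambda,
        region_n_cpgs=config.region_n_cpgs,
    )
    truth = generate_truth(study_cfg)
    state: dict = {}

    @stage("simulate")
    def _simulate():
        study = simulate_study(truth)
        files = {}
        for genotype, reps in study.items():
            for sample_id, records in reps.items():
                path = out / f"{sample_id}.bedGraph"
                write_methylation_bedgraph(records, path)
                files[sample_id] = str(path)
        truth.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
        genes = truth_genes(truth)
        write_gene_table(genes, out / "genes.tsv")
        write_expression_table(simulate_expression(truth), out / "expression.tsv")
        elements = simulate_elements(truth)
        for es in elements:
            write_bed(es.intervals, out / f"{es.name}.bed")
        track = simulate_signal_track(truth, {"af_target": 5.0})
        write_signal_bedgraph(signal_track_runs(track, truth.chrom), out / "signal.bedGraph")
        state.update(study=study, genes=genes, elements=elements, track=track)
        return {
            "samples": files,
            "n_cpgs": int(len(truth.positions)),
            "n_planted_regions": len(study_cfg.planted_regions),
        }

    @stage("call")
    def _call():
        study = state["study"]
        control = study["control"]
        results = {}
        info = {}
        for genotype in [g for g, _ in study_cfg.genotypes if g != "control"]:
            model = DifferentialMethylation.from_samples(
                control, study[genotype], config.caller
            )
            res = model.fit()
            res.to_bed(out / f"dmrs_{genotype}.bed")
            results[genotype] = ComparisonResult(f"{genotype}_vs_control", res.dmrs, res.dmcs)
            info[genotype] = {
                "analyzable_cpgs": model.matrix.n_cpgs,
                "dmcs": res.dmc_counts(),
                "dmrs": res.dmr_counts(),
            }
        state["results"] = results
        return info

    @stage("annotate")
    def _annotate():
        long_prom, core_prom = make_promoters(state["genes"], config.annotation)
        element_sets = list(state["elements"]) + [long_prom, core_prom]
        annotated = annotate_dmrs(
            state["results"]["ko"].dmrs, element_sets, config.annotation
        )
        table = count_by_class(annotated)
        table.to_csv(out / "annotation_counts.tsv", sep="\t")
        state["annotated_ko"] = annotated
        return {"counts": {c: row.to_dict() for c, row in table.iterrows()}}

    @stage("classify")
    def _classify():
        filtered, removed = transformation_filter(state["results"])
        labels, counts = classify_ca_af(filtered)
        classified_frame(labels + removed).to_csv(
            out / "classified_dmrs.tsv", sep="\t", index=False
        )
        counts.to_csv(out / "mechanism_counts.tsv", sep="\t")
        state["labels"] = labels
        return {
            "removed_transformation": len(removed),
            "counts": {d: row.to_dict() for d, row in counts.iterrows()},
        }

    @stage("integrate")
    def _integrate():
        gene_map = hypomethylated_promoter_genes(
            state["results"]["ko"].dmrs, state["genes"], config=config.annotation
        )
        from .io import read_expression_table

        expression = read_expression_table(out / "expression.tsv")
        records = assign_groups(gene_map, expression)
        group_frame(records).to_csv(out / "gene_groups.tsv", sep="\t", index=False)
        groups = {g: sum(1 for r in records if r.group == g) for g in ("G1", "G2", "G3")}
        return {"promoter_hypo_genes": len(gene_map), "groups": groups}

    @stage("profile")
    def _profile():
        track = SignalTrack({truth.chrom: state["track"]})
        af_regions = [
            r.interval
            for r in study_cfg.planted_regions
            if r.category == "af_target" and r.delta < 0
        ]
        none_regions = [
            r.interval for r in study_cfg.planted_regions if r.category == "none"
        ]
        if not af_regions or not none_regions:
            return {"skipped": "study lacks profiled categories"}
        prof_af = scaled_region_profile(af_regions, track)
        prof_none = scaled_region_profile(none_regions, track)
        pd.DataFrame(
            {
                "bin": prof_af.bin_labels,
                "mean_af": prof_af.mean,
                "sem_af": prof_af.sem,
                "mean_none": prof_none.mean,
                "sem_none": prof_none.sem,
            }
        ).to_csv(out / "profile_summary.tsv", sep="\t", index=False)
        _, region_p = compare_profiles(prof_af, prof_none)
        return {"region_mean_p": region_p}

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_fixtures(scale: str, outdir: str, seed: int = 0) -> Path:
    """Write the canonical input fixtures (samples, truth, genes, tables).

    ``tiny`` is a ~200-CpG, 3-region study for fast tests; ``default`` is
    the full ~50,000-CpG study driving the recovery suites.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study_cfg = default_study_config(seed=seed, scale=scale)
    truth = generate_truth(study_cfg)
    for genotype, reps in simulate_study(truth).items():
        for sample_id, records in reps.items():
            write_methylation_bedgraph(records, out / f"{sample_id}.bedGraph")
    truth.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
    write_gene_table(truth_genes(truth), out / "genes.tsv")
    write_expression_table(simulate_expression(truth), out / "expression.tsv")
    for es in simulate_elements(truth):
        write_bed(es.intervals, out / f"{es.name}.bed")
    track = simulate_signal_track(truth, {"af_target": 5.0})
    write_signal_bedgraph(signal_track_runs(track, truth.chrom), out / "signal.bedGraph")
    return out
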