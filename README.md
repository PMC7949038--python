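# dmrscape

Differential methylation analysis for multi-genotype whole-genome
bisulfite sequencing (WGBS) studies.

`dmrscape` is written for epigenomics groups comparing tumor methylomes of
several DNA-methyltransferase genotypes (e.g. an enzyme knockout, a
catalytically inactive knock-in, and a wild-type tumor) against a healthy
tissue control. From per-CpG methylation call tables it

1. calls **differentially methylated cytosines (DMCs)** and chains them
   into **differentially methylated regions (DMRs)** with a regional
   Mann–Whitney U test,
2. annotates DMRs to genomic elements (long/core promoters, exons,
   introns, CpG islands, enhancers, repeats),
3. applies **genotype set logic** that separates transformation-associated
   methylation changes from putative targets of the enzyme's *catalytic
   activity* (CA) versus its *accessory function* (AF — the recruitment of
   other methyltransferases),
4. integrates promoter hypomethylation with differential expression
   (G1/G2/G3 gene groups; hypomethylated-and-overexpressed gene lists),
5. aggregates histone/accessibility signal tracks over DMRs (length-scaled
   metagene profiles) and around TSSs.

A first-class **synthetic methylome generator** plants DMRs of known
width, effect size and genotype pattern, together with matched expression
tables and signal tracks, so the entire pipeline runs — and is validated —
at desk scale.

## The calls, precisely

Let $m_{is}$ and $u_{is}$ be methylated/unmethylated read counts of CpG
$i$ in sample $s$, and $\beta_{is} = m_{is}/(m_{is}+u_{is})$ the
methylation fraction. Only CpGs with coverage $\ge 5\times$ in **every**
sample are analyzed. For groups $A$ (control) and $B$ (tumor) with
per-group means $\bar\beta_i^A, \bar\beta_i^B$:

* **DMC**: $|\bar\beta_i^B - \bar\beta_i^A| \ge 0.30$ (inclusive);
  negative differences are *hypo*methylation in the tumor.
* **DMR**: a maximal run of $\ge 3$ same-direction DMCs with consecutive
  members $\le 50$ bp apart, kept when the two-sided Mann–Whitney U test
  over the member CpGs' per-sample fractions gives $p < 0.05$. The U test
  is exact (full enumeration, midranks) for $n_A + n_B \le 12$ and uses
  the tie-corrected normal approximation with continuity correction
  otherwise.

All thresholds live in `CallerConfig` and all coordinates are 0-based
half-open (BED-native).

## Worked example

```python
from dmrscape import DifferentialMethylation
from dmrscape.simulate import default_study_config, generate_truth, simulate_study

truth = generate_truth(default_study_config(seed=1))   # ~50k CpGs, planted DMRs
study = simulate_study(truth)                          # Poisson/binomial read counts
res = DifferentialMethylation.from_samples(study["control"], study["ko"]).fit()
print(res.summary())
```

```
Differential methylation results (group B vs group A)
========================================================
analyzable CpGs (>= 5x in all samples): 49913
group A: control_r0, control_r1
group B: ko_r0, ko_r1
DMC threshold |diff| >= 0.30; DMR: >= 3 DMCs, gap <= 50 bp, p(MWU) < 0.05
hypo DMCs:       212 (0.42% of CpGs)
hyper DMCs:        1 (0.0% of CpGs)
hypo DMRs:        45
hyper DMRs:        0
```

49,913 of ~50,000 simulated CpGs survive the all-sample 5× filter at 30×
mean coverage. The knockout genotype carries 45 planted hypomethylated
regions (accessory + catalytic + transformation + gene-tagged), and the
caller recovers all 45 as hypo DMRs with no false calls; the 212 hypo DMCs
are their member CpGs. `res.dmr_frame()` returns them as a BED6+ table:

```
chrom  start  end  name  score strand  n_cpgs  mean_diff    p_mwu direction
chrS1   5001 5062 dmr_0    427      .       5  -0.426541 0.000183      hypo
chrS1   7001 7054 dmr_1    400      .       5  -0.399641 0.000243      hypo
chrS1   9001 9082 dmr_2    438      .       5  -0.437634 0.000181      hypo
```

Downstream, `setlogic.transformation_filter` + `setlogic.classify_ca_af`
label DMRs across the wt/ko/ci genotype series, and
`integrate.assign_groups` splits promoter-hypomethylated genes into G1
(upregulated: fold change ≥ 2, p < 0.05), G2 (unchanged, control
FPKM > 0.2) and G3 (unchanged, FPKM < 0.2).

The same stages are available from a shell:

```sh
dmrscape run --scale default --seed 1 --outdir out/   # full synthetic study
dmrscape call --group-a c0.bedGraph --group-a c1.bedGraph \
              --group-b t0.bedGraph --group-b t1.bedGraph --out dmrs.bed
```

## Layout

| module | contents |
| --- | --- |
| `dmrscape.io`, `dmrscape.intervals` | bedGraph/BED/TSV dialects, interval contract |
| `dmrscape.simulate` | synthetic truth, read model, expression, signal tracks |
| `dmrscape.stats`, `dmrscape.calling` | Mann–Whitney U, DMC/DMR caller |
| `dmrscape.model` | `DifferentialMethylation` / `...Results` front end |
| `dmrscape.annotate` | promoter windows, 50%-overlap element annotation |
| `dmrscape.setlogic` | partition, transformation filter, CA/AF classification |
| `dmrscape.integrate` | G1/G2/G3 groups, hypomethylated-and-overexpressed lists |
| `dmrscape.profiles` | scaled-region and TSS metagene profiles, t-test comparison |
| `dmrscape.pipeline`, `dmrscape.cli` | orchestration, fixtures, `dmrscape` CLI |

Input conventions: methylation calls are MethylDackel-style 6-column
bedGraph (symmetric-CpG strand merging is assumed done upstream, the
MethylDackel default; fractions are recomputed from counts, never taken
from the percentage column). See `docs/methods.md` for the modeling
choices and their rationale.
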