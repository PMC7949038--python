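# Methods

## The procedure and its assumptions

`dmrscape` implements a two-group differential methylation contract on
per-CpG bisulfite counts, followed by comparative set logic across tumor
genotypes. The caller assumes:

* counts are strand-merged per CpG upstream (one record per CpG per
  sample);
* samples within a group are exchangeable replicates; group means are
  unweighted across samples (not coverage-weighted), so deep samples do
  not dominate a group;
* no smoothing and no shrinkage: the contract is the literal
  threshold-and-chain definition (a Metilene-style definition), not a
  segmentation or HMM model. This makes every call auditable against the
  stated thresholds — `calling.validate_dmr` re-asserts all of them on
  any emitted region;
* no multiple-testing correction is applied to regional p-values; the
  p < 0.05 cut is part of the region definition itself. Users needing
  genome-wide error control should treat the output as candidate regions.

## The regional test

The regional statistic is the two-sided Mann–Whitney U. Inputs are the
**pooled per-sample methylation fractions of the region's member CpGs**
(group A contributes `n_cpgs x n_samples_A` values). The per-CpG
group-mean variant (`CallerConfig(mwu_values="group_means")`) is also
available, but it is not the default for an arithmetic reason: with
group-mean vectors a 3-CpG region is a 3-vs-3 test whose exact two-sided
p-value can never go below 2/C(6,3) = 0.1, so the minimum region size of
three DMCs could never be significant at 0.05 and the stated definition
would be internally inconsistent. Pooling keeps 3-CpG regions reachable
and also behaves sensibly when one group has a single sample (a common
situation when the control is a public reference methylome).

The exact path enumerates all C(n, n_A) group assignments of the pooled
midranks (used for n ≤ 12), handling ties exactly; the approximate path
uses the tie-corrected normal approximation with a 0.5 continuity
correction. Both paths agree with an independent enumeration oracle and
with a reference implementation to machine precision (see the test
suite). If all pooled values are identical the test is uninformative and
p = 1.

## Chaining semantics

"Consecutive DMCs" is read as consecutive *DMCs*: an intervening retained
CpG that is not itself a DMC does not break a chain, because the
definition constrains only the distance between successive DMCs (≤ 50
bp) and their direction. The alternative reading — any retained non-DMC
CpG splits the run — is available as
`CallerConfig(strict_consecutive=True)`. Chains are maximal runs; adjacent
DMRs are never post-merged. Thresholds follow their printed forms:
|difference| ≥ 0.30 inclusive, p < 0.05 strict.

## Genotype set logic

Two DMRs in different comparisons are "the same region" when their
intervals overlap by ≥ 1 bp on the same chromosome in the same direction
— the bedtools-intersect default, adopted because no fractional criterion
is part of the definition. The transformation filter removes regions
matched across *all* tumor-vs-control comparisons before any mechanism
call is made; removal applies to every genotype's list. Mechanism labels
are then read off the genotype pattern:

| direction | pattern | label |
| --- | --- | --- |
| hypo | ko only (not ci, not wt) | accessory-function target |
| hypo | ko and ci | catalytic-activity target |
| hyper | ci but not ko | accessory-function target |
| hyper | wt only (not ko, not ci) | catalytic-activity target |
| any | everything else | unassigned |

Hypo labels are counted on the knockout list's units, hyper
accessory/catalytic labels on the ci/wt lists respectively; the labeling
is disjoint and exhaustive over every DMR entering the classifier.

## Promoter windows and element annotation

Long promoter: 1500 bp upstream to 500 bp downstream of the TSS; core
promoter: 300 bp upstream to 150 bp downstream; minus-strand windows
reflect around the TSS ([tss − down, tss + up)); windows are clipped at
the chromosome start. A DMR is assigned to an element class when the
**union** of that class's intervals covers ≥ 50% of the DMR's length —
the union (rather than best-single-interval) form makes the decision
invariant to how elements are split, and classes are independent
(multi-label), so no precedence hierarchy is imposed between, say,
promoter and exon.

For expression integration the long promoter is the gene–DMR linkage
window (`--window core` switches); when several DMRs hit one promoter the
largest-|effect| one represents the gene. The G2/G3 "unchanged" criterion
is operationally "not G1"; FPKM exactly at the 0.2 boundary goes to G2.

## Signal profiling

Region-body profiles rescale each region to 200 bp in 10-bp bins (20 body
bins) with 100 bp unscaled flanks (10 native bins each). Bin values are
exact fractional integrals of the piecewise-constant track
(coverage-weighted means), so regions shorter than the bin count are
handled by fractional spans rather than erroring. TSS profiles are
unscaled ±2000 bp windows, strand-oriented (minus-strand rows reversed);
DMR profiles are unstranded since DMRs carry no strand. SEM uses the
sample standard deviation (n − 1). Group comparison offers per-bin
two-sided t-tests and a whole-region test on per-region means, in both
Student and Welch flavours — both are exposed because either granularity
can be the quantity of interest.

## The synthetic generator

The generator emulates what the analysis assumes about real WGBS data:

* CpG positions with geometric spacing (default mean 100 bp, a realistic
  genome-wide CpG density) on one synthetic chromosome `chrS1`;
* bimodal baseline methylation: 70% of CpGs from Beta(9, 1) (highly
  methylated), 30% from Beta(1, 9) — defaults mimicking methylome
  bimodality, not claims about any particular tissue;
* planted regions of 5 CpGs at dense, island-like spacing (12–20 bp) with
  a tumor-vs-control shift of ±0.40; hypomethylated regions draw their
  baseline from the methylated component and hypermethylated ones from
  the unmethylated component, since methylation can only be lost where it
  exists (this also keeps the shift clip-free);
* reads per CpG per sample: coverage ~ Poisson(30), methylated count ~
  Binomial(coverage, true fraction) — a beta-binomial observation model
  whose beta stage is the fixed per-CpG truth; no extra per-read
  overdispersion by default;
* planted regions never overlap and sit ~2 kb apart (far beyond twice the
  chaining gap), so distinct truths cannot merge;
* the default study has four genotypes (control, wt, ko, ci; two
  replicates each) and ~69 regions: 10 transformation (shifted in all
  tumors), 10 accessory-hypo (ko only), 10 catalytic-hypo (ko and ci),
  8 accessory-hyper (ci only), 8 catalytic-hyper (wt only), 8 null, and
  15 ko-only regions tagged with G1/G2/G3 genes whose expression records
  are generated to satisfy their group definitions with lognormal FPKM
  noise. Signal tracks are noisy unit background times a flat in-region
  enrichment envelope with 50-bp linear ramps, so the mean in-region
  enrichment equals the configured multiplier.

What passing the recovery suites shows — and does not show: the planted
truth is piecewise-constant with independent binomial noise, so recovery
demonstrates that the caller and the set logic implement their
definitions correctly at realistic coverage and effect sizes. It does not
demonstrate robustness to correlated biological replicates, bisulfite
conversion error, copy-number distortion of fractions, or smoothly
varying methylation boundaries, none of which the generator emulates.

## Determinism and numerics

One global seed fans out to fixed per-purpose substreams
(`SeedSequence([seed, stage, genotype, replicate])`), so any sample is
reproducible in isolation and outputs are byte-identical across reruns.
The inclusive ≥ 0.30 comparison uses a 1e-12 guard against float error in
group means. Problem sizes were chosen so the full default study
(simulate + three comparisons + set logic) completes in a few seconds and
the complete test suite in well under a minute on one CPU.

## Known limitations

* Non-CpG methylation, smoothing-based callers and FDR estimation are out
  of scope.
* The cross-comparison matching rule (≥ 1 bp) is deliberately permissive;
  a reciprocal-fraction option would make "the same region" stricter and
  is a natural extension.
* Published genome-scale counts from real studies depend on the deposited
  data; this package reproduces their *arithmetic* (ratio summaries) and
  their *definitions* (validated on synthetic truth), not the genome-scale
  counts themselves.
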