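# Methods

## Study design and data model

The pipeline compares reduced-representation bisulfite sequencing (RRBS)
methylomes across three genotypes — wild type (WT), *Dnmt3b* knockout (KO)
and a catalytically inactive *Dnmt3b* knock-in (CI) — at a main embryonic
stage (E11.5), with an additional earlier WT stage (E10.5) for the de novo
analysis. Each sample is a list of per-CpG methylated/unmethylated read
counts. All internal coordinates are 0-based half-open; Bismark coverage
input (1-based) is converted on read, MethylDackel bedGraph is taken as-is,
and counts are always authoritative (percentages are recomputed). Input is
assumed destranded; an optional `destrand` step merges +/− calls at adjacent
positions by summing counts (off by default, since both dialects commonly
carry merged CpG counts already).

Analysis is restricted to CpGs covered at ≥ `min_cov` (default 15×; 10× in
cell-line mode) in **every** sample — the filter is applied per sample before
intersecting, so the common set is the intersection of adequately covered
sites. Within a group, replicate counts are pooled (summed) for group-level
percentages; per-sample percentages are retained because the rank test needs
sample-level values. Pooling rather than averaging is the default because
the pooled percentage is the coverage-weighted estimator and behaves better
under variable coverage; an averaging path exists via per-sample percents.

## DMC and DMR calling

A differentially methylated cytosine (DMC) is a common site with
|pooled test − pooled reference| ≥ `min_diff` (default 30 percentage points,
inclusive — ties at exactly 30.0 are DMCs). A DMR is a maximal run of DMCs
such that

* all members share a direction (hyper/hypo, sign of test − reference);
* consecutive members are ≤ `max_gap` bp apart (default 50; 100 in cell-line
  mode); an optional `max_span` caps total region length;
* the run is *consecutive among covered common CpGs*: an intervening covered
  CpG that is not a DMC breaks the run (strictest reading; `allow_skip`
  relaxes it);
* the run has ≥ `min_dmcs` members (default 3) and |mean member Δ| ≥
  `min_diff`;
* a two-sided Mann–Whitney U test comparing all per-sample per-CpG
  percentages of the two groups inside the run (e.g. 3 CpGs × 2 replicates =
  6 values per group) gives p < `alpha` (default 0.05).

The reported interval spans the first to last member CpG (half-open, end =
last position + 1). Segmentation is greedy maximal-run extension; under
maximality there are no ties to break. No multiple-testing correction is
applied anywhere — the published thresholds are raw p < 0.05 — though a
Benjamini–Hochberg helper is available.

One property worth recording: DMR *counts* are not monotone in `min_diff`.
Demoting a mid-run site from DMC to non-DMC can split one long run into two
runs that both qualify, so raising `min_diff` occasionally increases the DMR
count even though the DMC set strictly shrinks. The test suite asserts the
properties that do hold (DMC-set monotonicity in `min_diff`, DMR-count
monotonicity in `min_dmcs`).

## Statistical primitives

All tests used by the callers are implemented in `methylrescue.stats`; scipy
supplies only distribution functions (normal, t, chi-squared CDFs) and serves
as an independent oracle in the tests.

* **Mann–Whitney U**: exact null by the standard counting recursion when
  n₁ + n₂ ≤ 16 and the pooled data are tie-free — region-scale samples
  (3–10 CpGs × 2 replicates) sit exactly where the normal approximation is
  poor — otherwise a normal approximation with tie and continuity
  corrections. Two-sided p = 2·P(U ≤ min(U, n₁n₂ − U)), capped at 1.
* **Welch's t** (default two-sample test; pooled-variance Student available)
  with Welch–Satterthwaite degrees of freedom.
* **Chi-squared goodness of fit** for observed genotype counts against
  expected Mendelian ratios, df = k − 1.
* **Hypergeometric over-representation**: one-sided p = P(X ≥ k) for an
  overlap of k between gene sets of sizes n_A, n_B in a caller-supplied
  universe N, computed by log-space summation of the exact mass.
* **Uncentered-correlation average-linkage clustering**: distance
  d(x,y) = 1 − Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) (cosine distance), Lance–Williams
  average-linkage agglomeration, leaf order and Newick export; zero-norm rows
  get distance 1 to everything and are flagged.

## Rescue classification

A KO DMR is **strong** iff it overlaps any same-direction CI DMR by ≥ 1 bp,
otherwise **weak**; CI DMRs overlapping no KO DMR are counted separately and
excluded from the partition. Any-overlap is the weakest defensible criterion
given that the comparison is interval-level; a reciprocal-overlap fraction is
available as an option, as is a methylation-level re-test mode (CI-vs-WT mean
delta over the KO interval below `min_diff`) for users who read "rescued to
wild-type levels" as a level re-test rather than interval overlap.

## Annotation and ICR panel

Element assignment follows bedtools `-f` semantics: a DMR belongs to a kind
when a *single* element of that kind covers ≥ `min_overlap_frac` (default
0.5, inclusive) of the DMR length. Kinds are non-exclusive by default (an
exclusive priority mode exists). Promoter windows are strand-aware: long
promoter TSS−1500..+500, core promoter −300..+150, gene body TSS+500 to the
transcript end (empty and flagged when the transcript is shorter than
500 bp).

The ICR panel (22 germline + 9 somatic loci) is reported as the unweighted
mean of per-site pooled percentages per genotype. A locus is called
hypomethylated in KO when WT − KO ≥ 30 points and restored in CI when
|CI − WT| ≤ 10 points. The published per-locus calls are qualitative, so
both thresholds are declared, config-exposed assumptions chosen to reproduce
the described per-locus pattern; the same 10-point window is reused as the
restoration criterion in the temporal mechanism labels (one global knob).

## Temporal (de novo) analysis

Gains and losses between stages reuse the DMR caller with reference = early,
test = late within one genotype (common sites intersected across all four
samples). Each WT gain is then re-tested on the late-stage three-genotype
cohort by recomputing mean pooled percentages over the gain interval:
dependence = Dnmt3b-dependent iff KO − WT ≤ −`min_diff`; among dependent
gains, mechanism = accessory iff |CI − WT| < 10 points, catalytic otherwise.
Re-testing per region (rather than interval-overlap with the KO DMR list)
matches the per-region colouring logic of the source analysis. Intervals
with no covered CpG in a genotype are labeled no-data.

## Expression integration

The differential-expression caller is deliberately a stand-in for
count-based negative-binomial inference: log₂ fold change on group mean FPKM
with a 0.5 pseudocount and a Welch t-test on log₂(FPKM + 0.5) across
replicates, gates FC ≥ 2 (inclusive) and p < 0.05. The integration logic —
overlap statistics and the promoter-group classifier — is the substance; the
DE engine is labeled in the output metadata. Promoter groups for genes whose
long promoter is WT-methylated and KO-hypomethylated: wt level high iff mean
WT FPKM ≥ 1.0 (the high/low boundary is not published; 1 FPKM is the
conventional expressed/not-expressed line and is config-exposed);
expression_change up iff DE status is up with FC strictly > 2 (the >2-fold
inclusion rule). (high, unchanged) → Group 1, (low, unchanged) → Group 2,
(low, up) → Group 3; (high, up) genes fall outside the published scheme and
stay unassigned, as do genes absent from the matrix (flagged). Down-regulated
candidates fold into "unchanged". Group-mean expression is normalized to the
Group-3 WT mean.

## Chromatin profiles

Signal is consumed as fixed-bin bedGraph (no BAM/bigWig dependency; the
generator emits the same format). TSS profiles are strand-aware with
upstream negative; scaled profiles map each region body onto 100 bins with
unscaled ±100 bp flanks in 10 bp bins (a 1000 bp region scales as the
identity). Profiles report mean ± SEM across regions per bin; regions
contributing no data to a bin are excluded from that bin's n. Enrichment
comparisons summarize each region by its mean signal over the unscaled body
(flanks excluded) and apply Welch's t between region sets — per-region rather
than per-bin testing, chosen because region means are exchangeable units
(a per-bin mode is available through the profiles themselves).

## Synthetic data generator

The generator emulates the study design, not RRBS reads: 2 RRBS replicates
per genotype/stage, 3 expression replicates, and planted structure with
machine-readable truth. Everything is a deterministic function of the seed
(layout, methylation sampling, expression and tracks draw from separate
seed-derived streams).

* **Coverage**: negative binomial, mean 30×, size 50 (SD ≈ 7; ~1–2% of sites
  drop below the 15× filter per sample). Real RRBS coverage is more
  overdispersed; the mild choice keeps the common-site intersection dense so
  tests exercise the calling logic rather than missingness.
* **Methylation counts**: beta-binomial with precision (α+β) = 1000, giving a
  per-site percent SD of ≈ 9.2 points at 30× and 50% methylation — sampling
  noise dominates, biological overdispersion is mild.
* **Landscape**: 85% background methylation, 5% at CGIs and at pre-gain de
  novo targets (the bisulfite floor), 75% at ICR loci.
* **Planted regions**: 5 CpGs at fixed 25 bp spacing per region (span
  ~100 bp), placed in long promoters (one weak region per promoter-group
  gene), core promoters (de novo gains), and intergenic blocks with ≥ 500 bp
  separation; background CpGs avoid planted footprints ± 50 bp so truth
  intervals are clean. Defaults are the published totals: 4133 weak, 205
  strong, 110 CI-only (50-point effects), 133 gains and 196 losses (40-point
  effects), with 18 Dnmt3b-dependent gains of which 4 are catalytic.
* **ICR states** follow the published per-locus pattern: germline loci
  hypomethylated in KO (Gnas1a, Dlk1-Gtl2, 6330408a02Rik, AK008011; first
  two restored in CI) and 7/9 somatic loci hypomethylated (H19, Nesp, Gtl2,
  Igf2r restored), 40-point effects.
* **Expression**: log-normal FPKM (base median 10, ln-SD 0.5 across genes;
  ln-SD 0.2 replicate noise), 819 down and 219 independent up genes at
  4-fold among well-expressed genes — planted DE genes are drawn from an
  expressed base distribution because a 4-fold change at sub-FPKM levels is
  not detectable through the 0.5 pseudocount, which is a property of the
  method, not the generator — plus 34 Group-3 genes up at 8-fold (total 253
  up), and groups 150/163/34 at ~50 / ~0.2 FPKM WT levels. Three of the ten
  de novo promoter genes are down-regulated 4-fold between stages in WT.
* **Tracks**: baseline 1.0 with a slow sinusoid and mild noise, Gaussian
  bumps raising the local mean to the configured fold over the designated
  class: H3K27me3 3× over strong DMRs; H3K36me3 3×, H3K4me2/3 2× over weak
  DMRs.

What the generator does **not** emulate: read-level bisulfite conversion
error, strand asymmetry, realistic CpG density variation, correlated
region-level noise, genome-scale element composition (planted regions are
mostly intergenic with a repeat subset, so element distributions are
illustrative rather than genome-realistic), and count-based expression
uncertainty. Passing tests therefore demonstrate that the calling,
classification and integration logic recovers planted structure under the
stated noise model — not that the thresholds are optimal for real RRBS.

## Problem sizes and known limitations

The analysis drivers and acceptance runs use the full published region and
gene counts (~28k simulated CpGs, 12,000 genes); every stage completes in
seconds, and the whole acceptance script in under a minute. Unit and
property suites run on miniature cohorts (hundreds to ~2000 sites).

The main known limitation is the recovery ceiling of the temporal de novo
count. At the study conditions — a 40-point effect against the 30-point gate,
two replicates at 30×, 5-CpG regions — the per-CpG DMC detection probability
is ≈ 0.92 (the pooled-percent difference has an SD of ≈ 7 points, so the
gate sits only ~1.4 SD below the effect), and the ≥ 3-*consecutive*-DMC rule
turns a single mid-region miss into a broken run. Expected per-region
recovery is ≈ 0.85–0.90, and the pipeline accordingly recovers ~115–125 of
133 planted gains depending on seed (losses, starting from the noisier 85%
level, recover at a slightly lower rate). This is a property of the
published thresholds under the stated noise, not a calibration target: the
50-point rescue-class effects sit 2.6 SD above the gate and recover at
> 99%. The acceptance test for the temporal count states the expected value
and is allowed to fail at tight tolerance rather than loosening the
generator's conditions.

Other limitations: the weak/strong split is interval-based (no methylation
re-test by default); enrichment statements are validated on synthetic tracks
only, since published track normalization is unspecified; and the DE
stand-in will not reproduce count-based caller behaviour at low expression.
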