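# methylrescue

Analysis toolkit for a three-genotype RRBS study of DNA methyltransferase 3B
(Dnmt3b) in mouse embryogenesis: wild type (*Dnmt3b*⁺/⁺, "WT"), knockout
(*Dnmt3b*⁻/⁻, "KO") and a catalytically inactive knock-in (*Dnmt3b*^CI/CI,
"CI"). The question the pipeline answers is how much of Dnmt3b's contribution
to the embryonic methylome is **catalytic** (the enzyme must methylate DNA
itself) versus **accessory** (the protein must be present — e.g. to target or
stabilize other methyltransferases — but its own active site is dispensable,
the Dnmt3L paradigm).

The package is organised as an analysis project: every computation lives in
the library under `src/methylrescue/`, the numbered scripts under `analysis/`
are thin drivers that run the full study on synthetic cohorts with planted
truth, and `scripts/acceptance.py` recomputes the headline quantities.

## What it computes

Given per-CpG bisulfite calls (Bismark coverage or MethylDackel bedGraph),
restricted to CpGs with coverage ≥ 15× in **all** samples:

* **DMCs** — CpGs where the pooled group methylation difference
  |Δ| ≥ 30 percentage points (test − reference, counts pooled across
  replicates).
* **DMRs** — maximal runs of ≥ 3 consecutive same-direction DMCs with
  ≤ 50 bp between neighbours (an intervening covered non-DMC CpG breaks the
  run), |mean Δ| ≥ 30, and a two-sided Mann–Whitney U test on the per-sample
  per-CpG percentages with *p* < 0.05. The U test uses an exact
  enumeration-based null when *n*₁ + *n*₂ ≤ 16 and the data are tie-free.
* **Rescue classes** — a KO-vs-WT DMR is *strong* if it overlaps (≥ 1 bp) a
  same-direction CI-vs-WT DMR (methylation requires catalytic activity) and
  *weak* otherwise (the inactive allele restores it: accessory function).
  The restoration percentage is 100 · *n*_weak / *n*_total.
* **Annotation** — DMRs are assigned to long promoters (TSS −1500/+500),
  core promoters (−300/+150), gene bodies (TSS+500 to transcript end), exons,
  introns, CGIs, enhancers and repeats when a single element covers ≥ 50% of
  the DMR; a 22-germline + 9-somatic imprinted-control-region panel is
  reported per locus with hypomethylation (WT − KO ≥ 30 points) and CI
  restoration (|CI − WT| ≤ 10 points) calls.
* **Temporal (de novo) analysis** — gains/losses between two WT stages via
  the same caller; gains are re-tested per region in the late-stage KO/CI
  cohort for Dnmt3b dependence and accessory-vs-catalytic mechanism.
* **Expression integration** — a differential-expression stand-in (Welch *t*
  on log₂(FPKM + 0.5), gates FC ≥ 2 and *p* < 0.05), hypergeometric overlap
  of promoter-hypomethylated and up-regulated gene sets, and the Group 1/2/3
  promoter classifier (high/low WT FPKM × unchanged/up response).
* **Chromatin profiles** — TSS-centred and length-scaled meta-profiles
  (mean ± SEM) of binned signal tracks, and Welch tests of per-region mark
  enrichment between weak and strong DMRs.

A seed-deterministic generator (`methylrescue.simulate`) produces the whole
study download-free: negative-binomial coverage (mean 30×), beta-binomial
methylation counts, planted weak/strong/CI-only regions, temporal gains and
losses, per-ICR genotype states, planted fold changes and promoter-group
structure, and smooth signal tracks with per-class enrichment — all with
machine-readable truth tables.

## Worked example

```python
import methylrescue as mr

cfg = mr.SimConfig(seed=1)                      # the full study design
profiles, truth, genome = mr.simulate_methylation(cfg)
cohort = mr.build_cohort(
    {g: [profiles[f"{g}_E11.5_rep{i}"] for i in (1, 2)] for g in ("WT", "KO", "CI")},
    min_cov=15)

th = mr.Thresholds()                            # 15x, 30 pts, >=3 DMCs, <=50 bp, p<0.05
dmrs = {g: mr.segment_dmrs(mr.call_dmcs(cohort, "WT", g, th), cohort, "WT", g, th)
        for g in ("KO", "CI")}
labeled, summary = mr.classify_rescue(dmrs["KO"], dmrs["CI"])
print(summary.n_total, summary.n_weak, summary.n_strong,
      round(summary.restoration_pct, 1))
```

prints `4329 4120 209 95.2`: of 4329 hypomethylated KO DMRs, 4120 are
restored by the catalytically dead allele (95.2% — accessory function
dominates) and 209 remain hypomethylated in CI (catalytically dependent).
Running the numbered drivers (`python analysis/01_simulate_cohorts.py` … `07`)
prints the corresponding tables for every stage — e.g. the ICR panel report
calls 7/9 somatic ICRs hypomethylated in the knockout with 4 restored in CI,
and the temporal driver finds 123 de novo gains of which 18 are
Dnmt3b-dependent (14 accessory, 4 catalytic) — and writes them under
`results/`.

The same stages are exposed as a CLI for file-based inputs:

```bash
methylrescue simulate --seed 1 --out sim/
methylrescue call-dmrs --ref sim/WT_E11.5_rep1.bedGraph --ref sim/WT_E11.5_rep2.bedGraph \
    --test sim/KO_E11.5_rep1.bedGraph --test sim/KO_E11.5_rep2.bedGraph --out ko.bed
methylrescue rescue --ko ko.bed --ci ci.bed --out labeled.bed
```

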