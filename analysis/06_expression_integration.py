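"""Methylation-expression integration: DE stand-in, overlap statistics and
promoter groups.

Runs the Welch-on-log2-FPKM differential-expression stand-in (KO vs WT),
tests the overlap between promoter-hypomethylated and up-regulated genes
with the one-sided hypergeometric test, and classifies the
promoter-hypomethylated genes into Groups 1/2/3 by WT expression level and
response.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, SCRATCH, STUDY, THRESHOLDS, ensure_dirs, late_cohort, study_data

from methylrescue import (
    annotate_dmrs, call_dmcs, classify_promoter_groups, differential_expression,
    group_mean_expression_report, methylation_expression_overlap, segment_dmrs,
    simulate_expression,
)


def main():
    ensure_dirs()
    _, truth, genome = study_data()
    cohort = late_cohort()
    matrix, meta, _ = simulate_expression(STUDY, genome)

    de = differential_expression(matrix, meta, "WT", "KO", stage=STUDY.late_stage)
    de.to_csv(SCRATCH / "06_de_results.tsv", sep="\t", index=False)  # full 12k-gene table
    n_up = int((de["status"] == "up").sum())
    n_down = int((de["status"] == "down").sum())

    # genes with a KO-hypomethylated DMR in the long promoter
    dmcs = call_dmcs(cohort, "WT", "KO", THRESHOLDS)
    dmrs = segment_dmrs(dmcs, cohort, "WT", "KO", THRESHOLDS)
    ann = annotate_dmrs(dmrs[dmrs["direction"] == "hypo"], genome.catalog)
    hypo_genes = sorted(set(ann.loc[ann["long_promoter"] & (ann["long_promoter_gene"] != ""),
                                    "long_promoter_gene"]))
    counts, res = methylation_expression_overlap(hypo_genes, de, universe_n=len(matrix))
    counts.to_csv(RESULTS / "06_overlap_counts.tsv", sep="\t", index=False)

    assignments = classify_promoter_groups(hypo_genes, matrix, meta, de,
                                           fpkm_high_cutoff=1.0, stage=STUDY.late_stage)
    assignments.to_csv(RESULTS / "06_promoter_groups.tsv", sep="\t", index=False)
    group_sizes = assignments["group"].value_counts().sort_index()
    report = group_mean_expression_report(assignments, matrix, meta, stage=STUDY.late_stage)
    report.round(4).to_csv(RESULTS / "06_group_mean_expression.tsv", sep="\t", index=False)

    print(f"DE stand-in: {n_up} up, {n_down} down (planted "
          f"{STUDY.n_up_genes + STUDY.group_counts[2]} up, {STUDY.n_down_genes} down)")
    print(f"promoter-hypomethylated genes: {len(hypo_genes)}; overlap with up-regulated: "
          f"{counts.iloc[0].n_overlap} (hypergeometric p = {res.p_value:.3g})")
    print("promoter groups:", group_sizes.to_dict(),
          f"(planted {dict(zip(('1', '2', '3'), STUDY.group_counts))})")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
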