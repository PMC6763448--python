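"""Genomic annotation of DMRs and the imprinted-control-region panel.

Assigns KO and CI DMRs to genomic elements under the 50%-overlap rule,
tabulates per-chromosome counts, and reports per-ICR methylation with
hypomethylation/restoration calls for the 22 germline + 9 somatic loci.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, THRESHOLDS, ensure_dirs, late_cohort, study_data

from methylrescue import (
    annotate_dmrs, call_dmcs, chromosome_distribution, element_distribution,
    icr_report, segment_dmrs,
)


def main():
    ensure_dirs()
    _, truth, genome = study_data()
    cohort = late_cohort()

    dist_rows = []
    for test in ("KO", "CI"):
        dmcs = call_dmcs(cohort, "WT", test, THRESHOLDS)
        dmrs = segment_dmrs(dmcs, cohort, "WT", test, THRESHOLDS)
        ann = annotate_dmrs(dmrs, genome.catalog)
        dist = element_distribution(ann).rename(f"{test}_vs_WT")
        dist_rows.append(dist)
        chrom = chromosome_distribution(dmrs).rename(f"{test}_vs_WT")
        if test == "KO":
            chrom_table = chrom.to_frame()
        else:
            chrom_table = chrom_table.join(chrom, how="outer")
    element_table = pd.concat(dist_rows, axis=1).fillna(0).astype(int)
    element_table.to_csv(RESULTS / "04_element_distribution.tsv", sep="\t")
    chrom_table.fillna(0).astype(int).to_csv(RESULTS / "04_chromosome_distribution.tsv", sep="\t")

    report = icr_report(cohort, genome.icr_panel)
    report.round(2).to_csv(RESULTS / "04_icr_report.tsv", sep="\t", index=False)
    somatic = report[report["icr_class"] == "somatic"]
    germline = report[report["icr_class"] == "germline"]

    print("DMRs per element kind (non-exclusive):")
    print(element_table.to_string())
    print(f"\ngICRs hypomethylated in KO: {int(germline.hypo_in_ko.sum())}/22 "
          f"({', '.join(germline.loc[germline.hypo_in_ko, 'name'])})")
    print(f"sICRs hypomethylated in KO: {int(somatic.hypo_in_ko.sum())}/9 "
          f"({', '.join(somatic.loc[somatic.hypo_in_ko, 'name'])})")
    restored = somatic[somatic.hypo_in_ko & somatic.restored_in_ci]
    print(f"sICRs restored in CI: {len(restored)} ({', '.join(restored['name'])})")


if __name__ == "__main__":
    main()
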