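"""Weak/strong rescue classification of knockout DMRs.

Labels each KO DMR by whether the catalytically inactive allele restores its
methylation (weak: restored, evidence of accessory function; strong: still
hypomethylated in CI, evidence of catalytic dependence) and reports the
restoration percentage, alongside the worked example on the printed
4133-of-4338 split.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, SCRATCH, THRESHOLDS, ensure_dirs, late_cohort

from methylrescue import call_dmcs, classify_rescue, segment_dmrs
from methylrescue.io import write_dmr_bed
from methylrescue.rescue import restoration_report, summary_from_counts


def main():
    ensure_dirs()
    cohort = late_cohort()
    dmrs = {}
    for test in ("KO", "CI"):
        dmcs = call_dmcs(cohort, "WT", test, THRESHOLDS)
        dmrs[test] = segment_dmrs(dmcs, cohort, "WT", test, THRESHOLDS)
    labeled, summary = classify_rescue(dmrs["KO"], dmrs["CI"])
    write_dmr_bed(labeled, SCRATCH / "dmrs_KO_labeled.bed")
    report = restoration_report(summary)
    report.insert(0, "source", "synthetic study")

    printed = restoration_report(summary_from_counts(n_total=4338, n_weak=4133))
    printed.insert(0, "source", "printed counts")
    import pandas as pd
    both = pd.concat([report, printed], ignore_index=True)
    both.to_csv(RESULTS / "03_restoration_report.tsv", sep="\t", index=False)

    print(both.to_string(index=False))
    print(f"\n{summary.n_weak} of {summary.n_total} KO DMRs are restored by the inactive "
          f"allele ({summary.restoration_pct:.1f}%); {summary.n_strong} remain hypomethylated "
          f"(catalytically dependent); {summary.n_ci_only} CI DMRs overlap no KO DMR.")


if __name__ == "__main__":
    main()
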