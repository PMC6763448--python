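"""End-to-end orchestration: cohort build -> DMR calling (KO vs WT, CI vs WT)
-> rescue classification -> annotation + ICR panel -> temporal analysis ->
expression integration -> chromatin profiles.

Deterministic given inputs and configuration; every stage writes plain-text
outputs and the manifest echoes every parameter and per-stage row counts.
Stage failures halt with a stage-named error; outputs written before the
failure are preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .annotation import (
    AnnotationParams, ElementCatalog, annotate_dmrs, chromosome_distribution,
    element_distribution, icr_report, read_element_bed, read_icr_bed,
)
from .dmr import Thresholds, call_dmcs, segment_dmrs
from .expression import classify_promoter_groups, differential_expression, load_expression, methylation_expression_overlap
from .io import SampleProfile, build_cohort, read_bismark_cov, read_methyldackel_bedgraph, write_dmr_bed
from .profiles import compare_enrichment, load_signal_track
from .rescue import classify_rescue, restoration_report
from .temporal import classify_dependence, temporal_dmrs

READERS = {"bismark": read_bismark_cov, "methyldackel": read_methyldackel_bedgraph}


@dataclass
class SampleSpec:
    path: str
    sample_id: str
    genotype: str
    stage: str
    dialect: str = "methyldackel"


@dataclass
class RunConfig:
    """Validated run configuration; see pipeline.run_pipeline."""

    samples: list[SampleSpec]
    out_dir: str
    reference_genotype: str = "WT"
    test_genotypes: tuple[str, ...] = ("KO", "CI")
    main_stage: str = "E11.5"
    early_stage: str | None = None  # enables the temporal stage when set
    thresholds: Thresholds = field(default_factory=Thresholds)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    element_beds: dict[str, str] = field(default_factory=dict)  # kind -> BED path
    icr_bed: str | None = None
    expression_tsv: str | None = None
    track_paths: dict[str, str] = field(default_factory=dict)  # mark -> bedGraph
    fpkm_high_cutoff: float = 1.0
    restore_window: float = 10.0
    icr_hypo_drop: float = 30.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [s.path for s in self.samples if not Path(s.path).exists()]
        missing += [p for p in self.element_beds.values() if not Path(p).exists()]
        for p in (self.icr_bed, self.expression_tsv):
            if p and not Path(p).exists():
                missing.append(p)
        missing += [p for p in self.track_paths.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        if not self.samples:
            raise ValueError("no samples configured")
        genos = {s.genotype for s in self.samples if s.stage == self.main_stage}
        needed = {self.reference_genotype, *self.test_genotypes}
        if not needed <= genos:
            raise ValueError(f"missing genotypes at {self.main_stage}: {sorted(needed - genos)}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_profiles(config: RunConfig) -> dict[tuple[str, str], list[SampleProfile]]:
    out: dict[tuple[str, str], list[SampleProfile]] = {}
    for sample in config.samples:
        reader = READERS[sample.dialect]
        prof = reader(sample.path, sample_id=sample.sample_id,
                      genotype=sample.genotype, stage=sample.stage)
        out.setdefault((sample.genotype, sample.stage), []).append(prof)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dictionary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "thresholds": dataclasses.asdict(th),
            "annotation": dataclasses.asdict(config.annotation),
            "fpkm_high_cutoff": config.fpkm_high_cutoff,
            "restore_window": config.restore_window,
            "icr_hypo_drop": config.icr_hypo_drop,
            "seed": config.seed,
        },
        "stages": {},
    }
    profiles = _load_profiles(config)
    stage = "cohort"
    try:
        groups = {g: profiles[(g, config.main_stage)]
                  for g in (config.reference_genotype, *config.test_genotypes)}
        cohort = build_cohort(groups, min_cov=th.min_cov)
        cohort_out = cohort.sites.copy()
        for g in cohort.group_percent.columns:
            cohort_out[f"{g}_pct"] = cohort.group_percent[g].round(3)
        cohort_out.to_csv(out_dir / "cohort_sites.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_common_sites": cohort.n_sites}

        stage = "dmr_calling"
        dmr_tables = {}
        for g in config.test_genotypes:
            dmcs = call_dmcs(cohort, config.reference_genotype, g, th)
            dmrs = segment_dmrs(dmcs, cohort, config.reference_genotype, g, th)
            dmr_tables[g] = dmrs
            write_dmr_bed(dmrs, out_dir / f"dmrs_{g}_vs_{config.reference_genotype}.bed")
            manifest["stages"].setdefault(stage, {})[g] = {"n_dmcs": len(dmcs), "n_dmrs": len(dmrs)}

        stage = "rescue"
        if len(config.test_genotypes) >= 2:
            ko, ci = config.test_genotypes[0], config.test_genotypes[1]
            labeled, summary = classify_rescue(dmr_tables[ko], dmr_tables[ci])
            dmr_tables[ko] = labeled
            write_dmr_bed(labeled, out_dir / f"dmrs_{ko}_labeled.bed")
            restoration_report(summary).to_csv(out_dir / "restoration_report.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_total": summary.n_total, "n_weak": summary.n_weak,
                "n_strong": summary.n_strong, "n_ci_only": summary.n_ci_only,
            }

        stage = "annotation"
        if config.element_beds:
            catalog = ElementCatalog.concat(
                [read_element_bed(path, kind) for kind, path in config.element_beds.items()]
            )
            for g, dmrs in dmr_tables.items():
                ann = annotate_dmrs(dmrs, catalog, config.annotation)
                element_distribution(ann).to_csv(out_dir / f"element_distribution_{g}.tsv", sep="\t")
                chromosome_distribution(dmrs).to_csv(out_dir / f"chromosome_distribution_{g}.tsv", sep="\t")
            manifest["stages"][stage] = {"kinds": sorted(config.element_beds)}
        if config.icr_bed:
            panel = read_icr_bed(config.icr_bed)
            report = icr_report(cohort, panel,
                                wt=config.reference_genotype,
                                ko=config.test_genotypes[0], ci=config.test_genotypes[1],
                                hypo_drop=config.icr_hypo_drop, restore_window=config.restore_window)
            report.to_csv(out_dir / "icr_report.tsv", sep="\t", index=False)
            manifest["stages"]["icr"] = {"n_loci": len(report),
                                         "n_hypo_in_ko": int(report["hypo_in_ko"].sum())}

        stage = "temporal"
        if config.early_stage is not None:
            early = profiles[(config.reference_genotype, config.early_stage)]
            late = profiles[(config.reference_genotype, config.main_stage)]
            tdmrs, _ = temporal_dmrs(early, late, th)
            gains = tdmrs[tdmrs["direction"] == "gain"]
            labeled_gains = classify_dependence(
                gains, cohort, th, wt=config.reference_genotype,
                ko=config.test_genotypes[0], ci=config.test_genotypes[1],
                restore_window=config.restore_window)
            tdmrs.drop(columns=["members"]).to_csv(out_dir / "temporal_dmrs.tsv", sep="\t", index=False)
            labeled_gains.drop(columns=["members"]).to_csv(out_dir / "temporal_gains_labeled.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_gain": int((tdmrs["direction"] == "gain").sum()),
                "n_loss": int((tdmrs["direction"] == "loss").sum()),
                "n_dependent": int((labeled_gains["dependence"] == "dnmt3b_dependent").sum()),
            }

        stage = "expression"
        if config.expression_tsv:
            matrix, meta = load_expression(config.expression_tsv)
            de = differential_expression(matrix, meta, config.reference_genotype,
                                         config.test_genotypes[0], stage=config.main_stage)
            de.to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_up": int((de["status"] == "up").sum()),
                "n_down": int((de["status"] == "down").sum()),
                "method": de.attrs.get("method", ""),
            }

        stage = "profiles"
        if config.track_paths:
            prof_stats = []
            ko = config.test_genotypes[0]
            labeled = dmr_tables[ko]
            if "label" in labeled.columns:
                strong = labeled[labeled["label"] == "strong"]
                weak = labeled[labeled["label"] == "weak"]
                for mark, path in config.track_paths.items():
                    track = load_signal_track(path, mark)
                    if len(strong) >= 2 and len(weak) >= 2:
                        res = compare_enrichment(track, strong, weak)
                        prof_stats.append({"mark": mark, "statistic": res.statistic, "p_value": res.p_value})
            if prof_stats:
                pd.DataFrame(prof_stats).to_csv(out_dir / "enrichment_strong_vs_weak.tsv", sep="\t", index=False)
                manifest["stages"][stage] = {"n_marks": len(prof_stats)}
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
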