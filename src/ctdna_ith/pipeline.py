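"""End-to-end orchestration: filter -> spatial -> concordance -> temporal.

``run_cohort`` takes per-patient variant tables plus the sample sheet and
returns every result table the pipeline produces; ``run_directory`` is the
file-based front end (VCF directory + sample sheet + annotation + COSMIC
list) used by the CLI.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import panels
from .ctdna_concordance import (
    ConcordanceSummary,
    cohort_concordance,
    concordance,
    concordance_frame,
)
from .io_formats import (
    PatientVariantTable,
    SampleSheet,
    read_annotation_table,
    read_cosmic_list,
    read_multisample_vcf,
    read_sample_sheet,
    write_results,
)
from .somatic_filter import (
    FilterThresholds,
    apply_filter_cascade,
    build_presence_matrix,
    filter_trace_frame,
)
from .spatial_ith import (
    classify_spatial,
    cohort_heterogeneity,
    gene_level_summary,
    heterogeneity_summary,
    high_frequency_subset,
    patient_summary_frame,
    pooled_heterogeneity,
    spatial_class_frame,
)
from .temporal_tracking import (
    build_trajectories,
    label_variants,
    molecular_recurrence,
    recurrence_frame,
    trajectory_frame,
)


@dataclass
class PipelineConfig:
    """Everything tunable about an analysis run (YAML-loadable)."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    annotation_filter: str = "cosmic_subset"  # spatial summary denominator
    restrict_concordance_to_cosmic: bool = True
    restrict_concordance_to_panel: bool = True
    qualifying_variants: str = "cosmic_subset"  # molecular recurrence calling
    strict_acquired: bool = False
    welch: bool = False

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            "thresholds": {
                k: getattr(self.thresholds, k)
                for k in (
                    "germline_af_max", "germline_min_depth", "min_supporting_reads",
                    "lowcov_af_min", "lowcov_min_reads", "final_vaf_min",
                    "high_freq_vaf", "restore_removed_with_support",
                )
            },
            "annotation_filter": self.annotation_filter,
            "restrict_concordance_to_cosmic": self.restrict_concordance_to_cosmic,
            "restrict_concordance_to_panel": self.restrict_concordance_to_panel,
            "qualifying_variants": self.qualifying_variants,
            "strict_acquired": self.strict_acquired,
            "welch": self.welch,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class CohortResults:
    """All result tables of one pipeline run, ready for :func:`write_results`."""

    filter_trace: pd.DataFrame
    spatial_classes: pd.DataFrame
    patient_summary: pd.DataFrame
    gene_summary: pd.DataFrame
    concordance: pd.DataFrame
    trajectories: pd.DataFrame
    recurrence_calls: pd.DataFrame
    cohort_heterogeneity: "pd.Series | None" = None
    per_patient: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "filter_trace": self.filter_trace,
            "spatial_classes": self.spatial_classes,
            "patient_summary": self.patient_summary,
            "gene_summary": self.gene_summary,
            "concordance": self.concordance,
            "trajectories": self.trajectories,
            "recurrence_calls": self.recurrence_calls,
        }


def run_patient(
    table: PatientVariantTable,
    sheet: SampleSheet,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run every stage for one patient; returns a dict of stage outputs."""
    thresholds = config.thresholds
    decisions = apply_filter_cascade(table, sheet, thresholds)
    presence = build_presence_matrix(table, decisions, thresholds)
    out: dict = {"decisions": decisions, "presence": presence}

    pid = table.patient_id
    if sheet.core_sample(pid) and sheet.margin_sample(pid):
        classes = classify_spatial(presence, sheet)
        out["classes"] = classes
        out["summary"] = heterogeneity_summary(
            classes,
            scope="per_patient",
            annotations=table.annotations,
            annotation_filter=config.annotation_filter,
        )
        out["highfreq"] = high_frequency_subset(table, presence, sheet, thresholds)
        out["concordance"] = concordance(
            presence,
            classes,
            out["highfreq"],
            table,
            sheet,
            restrict_to_cosmic=config.restrict_concordance_to_cosmic,
            panel_genes=(
                panels.plasma_panel_genes()
                if config.restrict_concordance_to_panel
                else None
            ),
        )
        labels, plasma_a_only = label_variants(
            presence, classes, sheet, strict_acquired=config.strict_acquired
        )
        out["labels"] = labels
        out["plasma_a_only"] = plasma_a_only
        out["trajectories"] = build_trajectories(presence, labels, table, sheet)
        if sheet.recurrence_day(pid) is not None:
            out["recurrence"] = molecular_recurrence(
                out["trajectories"], sheet, pid, qualifying=config.qualifying_variants
            )
    return out


def run_cohort(
    tables: Mapping[str, PatientVariantTable],
    sheet: SampleSheet,
    config: PipelineConfig = PipelineConfig(),
    gene_panel: Sequence[str] | None = None,
) -> CohortResults:
    per_patient = {pid: run_patient(t, sheet, config) for pid, t in tables.items()}

    classes_by_patient = {
        pid: r["classes"] for pid, r in per_patient.items() if "classes" in r
    }
    annotations_by_patient = {
        pid: tables[pid].annotations for pid in classes_by_patient
    }
    summaries = {
        pid: r["summary"] for pid, r in per_patient.items() if "summary" in r
    }
    conc: list[ConcordanceSummary] = [
        r["concordance"]
        for r in per_patient.values()
        if r.get("concordance") is not None
    ]
    conc_frame = concordance_frame(conc)
    if conc:
        cohort_row = concordance_frame([cohort_concordance(conc)])
        conc_frame = pd.concat([conc_frame, cohort_row], ignore_index=True)

    trajs = [t for r in per_patient.values() for t in r.get("trajectories", [])]
    calls = [r["recurrence"] for r in per_patient.values() if "recurrence" in r]

    results = CohortResults(
        filter_trace=pd.concat(
            [
                filter_trace_frame(tables[pid], r["decisions"], sheet)
                for pid, r in per_patient.items()
            ],
            ignore_index=True,
        ),
        spatial_classes=spatial_class_frame(classes_by_patient, annotations_by_patient),
        patient_summary=patient_summary_frame(summaries),
        gene_summary=gene_level_summary(
            classes_by_patient,
            annotations_by_patient,
            gene_panel or panels.tcga_hnscc_genes(),
            annotation_filter=config.annotation_filter,
        ),
        concordance=conc_frame,
        trajectories=trajectory_frame(trajs),
        recurrence_calls=recurrence_frame(calls),
        per_patient=per_patient,
    )
    cohort = cohort_heterogeneity(summaries.values())
    pooled = pooled_heterogeneity(
        classes_by_patient, annotations_by_patient, config.annotation_filter
    )
    results.cohort_heterogeneity = pd.Series(
        {
            "n_patients": cohort.n_patients,
            "mean_heterogeneity_rate": cohort.heterogeneity_rate,
            "mean_prop_core_only": cohort.prop_core_only,
            "mean_prop_margin_only": cohort.prop_margin_only,
            "mean_prop_shared": cohort.prop_shared,
            "rate_min": cohort.rate_min,
            "rate_max": cohort.rate_max,
            "pooled_heterogeneity_rate": pooled.heterogeneity_rate,
        }
    )
    return results


def load_cohort(
    vcf_dir: str | os.PathLike,
    sample_sheet_path: str | os.PathLike,
    annotation_path: str | os.PathLike | None = None,
    cosmic_list_path: str | os.PathLike | None = None,
) -> tuple[dict[str, PatientVariantTable], SampleSheet]:
    """Read a cohort directory (one VCF per patient) into variant tables."""
    sheet = read_sample_sheet(sample_sheet_path)
    cosmic = read_cosmic_list(cosmic_list_path) if cosmic_list_path else set()
    annotations = (
        read_annotation_table(annotation_path, cosmic) if annotation_path else {}
    )
    tables: dict[str, PatientVariantTable] = {}
    paths = sorted(glob.glob(os.path.join(os.fspath(vcf_dir), "*.vcf")))
    if not paths:
        raise FileNotFoundError(f"no .vcf files in {vcf_dir}")
    for path in paths:
        table = read_multisample_vcf(path, sheet)
        table.annotate(annotations)
        tables[table.patient_id] = table
    return tables, sheet


def run_directory(
    vcf_dir,
    sample_sheet_path,
    annotation_path=None,
    cosmic_list_path=None,
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
) -> CohortResults:
    tables, sheet = load_cohort(vcf_dir, sample_sheet_path, annotation_path, cosmic_list_path)
    results = run_cohort(tables, sheet, config)
    if outdir is not None:
        out_tables = dict(results.tables())
        if results.cohort_heterogeneity is not None:
            out_tables["cohort_summary"] = (
                results.cohort_heterogeneity.rename("value").rename_axis("metric").reset_index()
            )
        write_results(out_tables, outdir)
    return results
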