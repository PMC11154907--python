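"""Spatial intra-tumoural heterogeneity (ITH) from core/margin exclusivity.

ITH is quantified as the proportion of tumour-present variants exclusive to
a single tumour sub-site (core or margin, but not both).  Proportions can be
restricted to the HNSCC COSMIC subset, summarised per gene (mean over the
patients carrying variants of that gene), per patient, or cohort-wide as an
unweighted mean over patients with min-max range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .io_formats import Annotation, PatientVariantTable, SampleSheet, VariantKey
from .somatic_filter import FilterThresholds, PresenceMatrix


class SpatialClass(str, Enum):
    CORE_ONLY = "CORE_ONLY"
    MARGIN_ONLY = "MARGIN_ONLY"
    SHARED = "SHARED"
    NOT_IN_TUMOUR = "NOT_IN_TUMOUR"


EXCLUSIVE_CLASSES = frozenset({SpatialClass.CORE_ONLY, SpatialClass.MARGIN_ONLY})
TUMOUR_CLASSES = frozenset(
    {SpatialClass.CORE_ONLY, SpatialClass.MARGIN_ONLY, SpatialClass.SHARED}
)


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Core-only / margin-only / shared partition of tumour-present variants.

    Proportions are over tumour-present variants only and sum to 1;
    ``heterogeneity_rate`` is the site-exclusive fraction (1 - prop_shared).
    All proportions are NaN when no variant is tumour-present.  Cohort-scope
    summaries carry the unweighted mean over patients plus the min-max range.
    """

    scope: str  # per_gene | per_patient | cohort
    n_variants: int
    prop_core_only: float
    prop_margin_only: float
    prop_shared: float
    rate_min: float = math.nan
    rate_max: float = math.nan
    n_patients: int = 1

    @property
    def heterogeneity_rate(self) -> float:
        return self.prop_core_only + self.prop_margin_only

    @property
    def defined(self) -> bool:
        return not math.isnan(self.prop_shared)


def classify_spatial(
    presence: PresenceMatrix, sample_sheet: SampleSheet
) -> dict[VariantKey, SpatialClass]:
    """Assign each variant a sub-site exclusivity class from presence calls."""
    pid = presence.patient_id
    core = sample_sheet.core_sample(pid)
    margin = sample_sheet.margin_sample(pid)
    if core is None or margin is None:
        raise ValueError(f"patient {pid}: both CORE and MARGIN samples are required")
    out: dict[VariantKey, SpatialClass] = {}
    for v in presence.variants:
        in_core = presence.present(v, core)
        in_margin = presence.present(v, margin)
        if in_core and in_margin:
            out[v] = SpatialClass.SHARED
        elif in_core:
            out[v] = SpatialClass.CORE_ONLY
        elif in_margin:
            out[v] = SpatialClass.MARGIN_ONLY
        else:
            out[v] = SpatialClass.NOT_IN_TUMOUR
    return out


def _select(
    classes: Mapping[VariantKey, SpatialClass],
    annotations: Mapping[VariantKey, Annotation] | None,
    annotation_filter: str,
) -> list[SpatialClass]:
    if annotation_filter not in ("all", "cosmic_subset"):
        raise ValueError(f"unknown annotation_filter {annotation_filter!r}")
    out = []
    for v, cls in classes.items():
        if annotation_filter == "cosmic_subset":
            ann = (annotations or {}).get(v, Annotation())
            if not ann.in_hnscc_cosmic_subset:
                continue
        out.append(cls)
    return out


def heterogeneity_summary(
    classes: Mapping[VariantKey, SpatialClass],
    scope: str = "per_patient",
    annotations: Mapping[VariantKey, Annotation] | None = None,
    annotation_filter: str = "all",
) -> HeterogeneitySummary:
    """Partition proportions for one patient (plasma-only variants excluded)."""
    selected = _select(classes, annotations, annotation_filter)
    tumour = [c for c in selected if c in TUMOUR_CLASSES]
    n = len(tumour)
    if n == 0:
        return HeterogeneitySummary(scope, 0, math.nan, math.nan, math.nan)
    return HeterogeneitySummary(
        scope=scope,
        n_variants=n,
        prop_core_only=sum(c is SpatialClass.CORE_ONLY for c in tumour) / n,
        prop_margin_only=sum(c is SpatialClass.MARGIN_ONLY for c in tumour) / n,
        prop_shared=sum(c is SpatialClass.SHARED for c in tumour) / n,
    )


def cohort_heterogeneity(
    patient_summaries: Iterable[HeterogeneitySummary],
) -> HeterogeneitySummary:
    """Unweighted mean over patients with >= 1 tumour-present variant."""
    defined = [s for s in patient_summaries if s.defined]
    if not defined:
        return HeterogeneitySummary("cohort", 0, math.nan, math.nan, math.nan, n_patients=0)
    k = len(defined)
    rates = [s.heterogeneity_rate for s in defined]
    return HeterogeneitySummary(
        scope="cohort",
        n_variants=sum(s.n_variants for s in defined),
        prop_core_only=sum(s.prop_core_only for s in defined) / k,
        prop_margin_only=sum(s.prop_margin_only for s in defined) / k,
        prop_shared=sum(s.prop_shared for s in defined) / k,
        rate_min=min(rates),
        rate_max=max(rates),
        n_patients=k,
    )


def pooled_heterogeneity(
    classes_by_patient: Mapping[str, Mapping[VariantKey, SpatialClass]],
    annotations_by_patient: Mapping[str, Mapping[VariantKey, Annotation]] | None = None,
    annotation_filter: str = "all",
) -> HeterogeneitySummary:
    """Variant-pooled cohort proportions (secondary to the per-patient mean)."""
    pooled: list[SpatialClass] = []
    for pid, classes in classes_by_patient.items():
        ann = (annotations_by_patient or {}).get(pid)
        pooled.extend(
            c for c in _select(classes, ann, annotation_filter) if c in TUMOUR_CLASSES
        )
    n = len(pooled)
    if n == 0:
        return HeterogeneitySummary("cohort", 0, math.nan, math.nan, math.nan, n_patients=0)
    return HeterogeneitySummary(
        scope="cohort",
        n_variants=n,
        prop_core_only=sum(c is SpatialClass.CORE_ONLY for c in pooled) / n,
        prop_margin_only=sum(c is SpatialClass.MARGIN_ONLY for c in pooled) / n,
        prop_shared=sum(c is SpatialClass.SHARED for c in pooled) / n,
        n_patients=len(classes_by_patient),
    )


def gene_level_summary(
    classes_by_patient: Mapping[str, Mapping[VariantKey, SpatialClass]],
    annotations_by_patient: Mapping[str, Mapping[VariantKey, Annotation]],
    gene_panel: Iterable[str],
    annotation_filter: str = "cosmic_subset",
) -> pd.DataFrame:
    """Per-gene mean exclusivity across patients.

    For each gene, each patient contributes the exclusive (core-only +
    margin-only) proportion over that patient's tumour-present variants of
    the gene; the gene summary is the unweighted mean over contributing
    patients.  Patients with no tumour-present variant of the gene are
    excluded from that gene's mean.  Genes with no variants cohort-wide get
    n_patients 0 and an undefined mean.
    """
    rows = []
    for gene in gene_panel:
        per_patient = []
        n_variants = 0
        for pid, classes in classes_by_patient.items():
            anns = annotations_by_patient.get(pid, {})
            cls = [
                c
                for v, c in classes.items()
                if anns.get(v, Annotation()).gene == gene
                and c in TUMOUR_CLASSES
                and (
                    annotation_filter == "all"
                    or anns.get(v, Annotation()).in_hnscc_cosmic_subset
                )
            ]
            if cls:
                n_variants += len(cls)
                per_patient.append(sum(c in EXCLUSIVE_CLASSES for c in cls) / len(cls))
        rows.append(
            {
                "gene": gene,
                "n_patients": len(per_patient),
                "n_variants": n_variants,
                "mean_exclusivity": (
                    sum(per_patient) / len(per_patient) if per_patient else math.nan
                ),
                "min_exclusivity": min(per_patient, default=math.nan),
                "max_exclusivity": max(per_patient, default=math.nan),
            }
        )
    return pd.DataFrame(rows)


def high_frequency_subset(
    table: PatientVariantTable,
    presence: PresenceMatrix,
    sample_sheet: SampleSheet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> set[VariantKey]:
    """Tumour-present variants with VAF strictly above 5% in core or margin.

    A crude clonality proxy: in the absence of formal subclonal
    deconvolution, variants above this frequency in at least one sub-site
    are treated as high-frequency (dominant-clone) variants.
    """
    pid = table.patient_id
    sites = [s for s in (sample_sheet.core_sample(pid), sample_sheet.margin_sample(pid)) if s]
    out: set[VariantKey] = set()
    for v in table.variants:
        if not presence.present_in_any(v, sites):
            continue
        for s in sites:
            vaf = table.call(v, s).vaf
            if not math.isnan(vaf) and vaf > thresholds.high_freq_vaf:
                out.add(v)
                break
    return out


def compare_exclusivity(
    group_a: Iterable[float], group_b: Iterable[float], welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test between two groups of per-patient proportions.

    Student (pooled-variance) by default; Welch via flag.  Returns (t, p).
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def spatial_class_frame(
    classes_by_patient: Mapping[str, Mapping[VariantKey, SpatialClass]],
    annotations_by_patient: Mapping[str, Mapping[VariantKey, Annotation]] | None = None,
) -> pd.DataFrame:
    """Variant-level spatial classification table (TSV-ready)."""
    rows = []
    for pid, classes in classes_by_patient.items():
        anns = (annotations_by_patient or {}).get(pid, {})
        for v, c in classes.items():
            ann = anns.get(v, Annotation())
            rows.append(
                {
                    "patient_id": pid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": ann.gene,
                    "cosmic_id": ann.cosmic_id,
                    "in_hnscc_cosmic_subset": ann.in_hnscc_cosmic_subset,
                    "spatial_class": c.value,
                }
            )
    return pd.DataFrame(rows)


def patient_summary_frame(
    summaries: Mapping[str, HeterogeneitySummary]
) -> pd.DataFrame:
    rows = []
    for pid, s in summaries.items():
        rows.append(
            {
                "patient_id": pid,
                "n_variants": s.n_variants,
                "prop_core_only": s.prop_core_only,
                "prop_margin_only": s.prop_margin_only,
                "prop_shared": s.prop_shared,
                "heterogeneity_rate": s.heterogeneity_rate,
            }
        )
    return pd.DataFrame(rows)
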