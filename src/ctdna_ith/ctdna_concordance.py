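"""Baseline plasma (ctDNA) vs tumour variant concordance.

Reproduces the tumour-informed/naive hybrid comparison: how much of the
tumour's variant burden the baseline plasma sample detects, how much of the
high-frequency (inferred clonal) burden it detects, how spatially exclusive
the detected variants are, and what fraction of plasma variants were never
seen in either tumour sub-site.

By default the comparison is restricted to the COSMIC HNSCC subset within
the 9-gene plasma panel — the plasma assay cannot see loci outside its
panel, so tumour variants outside it are excluded from every denominator.
Rates with zero denominators are undefined (NaN), never zero, and are
excluded from cohort means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PatientVariantTable, SampleSheet, VariantKey
from .somatic_filter import PresenceMatrix
from .spatial_ith import EXCLUSIVE_CLASSES, SpatialClass


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else math.nan


@dataclass(frozen=True)
class ConcordanceSummary:
    """Plasma/tumour overlap metrics for one patient or the cohort.

    detection_rate_all        |plasma ∩ tumour| / |tumour|
    detection_rate_highfreq   |plasma ∩ tumour_highfreq| / |tumour_highfreq|
    exclusivity_among_detected  fraction of detected tumour variants that are
                              core-only or margin-only
    plasma_only_fraction      |plasma \\ tumour| / |plasma|
    """

    patient_id: str
    n_tumour: int
    n_tumour_highfreq: int
    n_plasma: int
    detection_rate_all: float
    detection_rate_highfreq: float
    exclusivity_among_detected: float
    plasma_only_fraction: float
    rate_all_min: float = math.nan
    rate_all_max: float = math.nan
    n_patients: int = 1


def concordance(
    presence: PresenceMatrix,
    classes: Mapping[VariantKey, SpatialClass],
    highfreq_set: set[VariantKey],
    table: PatientVariantTable,
    sample_sheet: SampleSheet,
    baseline_timepoint: str = "A",
    restrict_to_cosmic: bool = True,
    panel_genes: Sequence[str] | None = None,
) -> ConcordanceSummary | None:
    """Per-patient concordance between baseline plasma and tumour variants.

    Returns None (the patient is skipped) when no baseline plasma sample
    exists.  ``panel_genes`` restricts the variant universe to the plasma
    assay's genes; pass None to disable the restriction.
    """
    pid = presence.patient_id
    plasma = sample_sheet.plasma_samples(pid).get(baseline_timepoint)
    if plasma is None:
        return None

    def in_universe(v: VariantKey) -> bool:
        ann = table.annotation(v)
        if restrict_to_cosmic and not ann.in_hnscc_cosmic_subset:
            return False
        if panel_genes is not None and ann.gene not in panel_genes:
            return False
        return True

    universe = [v for v in presence.variants if in_universe(v)]
    tumour = {v for v in universe if classes.get(v) in
              (SpatialClass.CORE_ONLY, SpatialClass.MARGIN_ONLY, SpatialClass.SHARED)}
    plasma_set = {v for v in universe if presence.present(v, plasma.sample_name)}
    highfreq = {v for v in highfreq_set if v in tumour}

    detected = plasma_set & tumour
    detected_hf = plasma_set & highfreq
    exclusive = {v for v in detected if classes.get(v) in EXCLUSIVE_CLASSES}

    return ConcordanceSummary(
        patient_id=pid,
        n_tumour=len(tumour),
        n_tumour_highfreq=len(highfreq),
        n_plasma=len(plasma_set),
        detection_rate_all=_rate(len(detected), len(tumour)),
        detection_rate_highfreq=_rate(len(detected_hf), len(highfreq)),
        exclusivity_among_detected=_rate(len(exclusive), len(detected)),
        plasma_only_fraction=_rate(len(plasma_set - tumour), len(plasma_set)),
    )


def cohort_concordance(
    summaries: Iterable[ConcordanceSummary],
) -> ConcordanceSummary:
    """Unweighted cohort means over patients with defined rates per field."""
    per_patient = [s for s in summaries if s is not None]
    if not per_patient:
        raise ValueError("no patient summaries with a baseline plasma sample")

    def field_mean(name: str) -> float:
        vals = [getattr(s, name) for s in per_patient]
        return _mean([x for x in vals if not math.isnan(x)])

    rates = [s.detection_rate_all for s in per_patient if not math.isnan(s.detection_rate_all)]
    return ConcordanceSummary(
        patient_id="cohort",
        n_tumour=sum(s.n_tumour for s in per_patient),
        n_tumour_highfreq=sum(s.n_tumour_highfreq for s in per_patient),
        n_plasma=sum(s.n_plasma for s in per_patient),
        detection_rate_all=field_mean("detection_rate_all"),
        detection_rate_highfreq=field_mean("detection_rate_highfreq"),
        exclusivity_among_detected=field_mean("exclusivity_among_detected"),
        plasma_only_fraction=field_mean("plasma_only_fraction"),
        rate_all_min=min(rates, default=math.nan),
        rate_all_max=max(rates, default=math.nan),
        n_patients=len(per_patient),
    )


def leave_one_out_means(
    summaries: Sequence[ConcordanceSummary], field: str = "detection_rate_highfreq"
) -> dict[str, float]:
    """Cohort mean of ``field`` with each patient excluded in turn."""
    out: dict[str, float] = {}
    for skip in summaries:
        vals = [
            getattr(s, field)
            for s in summaries
            if s.patient_id != skip.patient_id and not math.isnan(getattr(s, field))
        ]
        out[skip.patient_id] = _mean(vals)
    return out


def concordance_frame(summaries: Iterable[ConcordanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "patient_id": s.patient_id,
                "n_tumour": s.n_tumour,
                "n_tumour_highfreq": s.n_tumour_highfreq,
                "n_plasma": s.n_plasma,
                "detection_rate_all": s.detection_rate_all,
                "detection_rate_highfreq": s.detection_rate_highfreq,
                "exclusivity_among_detected": s.exclusivity_among_detected,
                "plasma_only_fraction": s.plasma_only_fraction,
            }
        )
    return pd.DataFrame(rows)


def venn_counts(
    presence: PresenceMatrix,
    sample_sheet: SampleSheet,
    table: PatientVariantTable,
    baseline_timepoint: str = "A",
    restrict_to_cosmic: bool = True,
    panel_genes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Counts for the 7 regions of the core/margin/plasma Venn diagram."""
    pid = presence.patient_id
    core = sample_sheet.core_sample(pid)
    margin = sample_sheet.margin_sample(pid)
    plasma = sample_sheet.plasma_samples(pid).get(baseline_timepoint)
    sets = {
        "core": presence.present_set(core) if core else set(),
        "margin": presence.present_set(margin) if margin else set(),
        "plasma": presence.present_set(plasma.sample_name) if plasma else set(),
    }
    if restrict_to_cosmic or panel_genes is not None:
        def keep(v: VariantKey) -> bool:
            ann = table.annotation(v)
            if restrict_to_cosmic and not ann.in_hnscc_cosmic_subset:
                return False
            return panel_genes is None or ann.gene in panel_genes
        sets = {k: {v for v in s if keep(v)} for k, s in sets.items()}
    c, m, p = sets["core"], sets["margin"], sets["plasma"]
    return {
        "core_only": len(c - m - p),
        "margin_only": len(m - c - p),
        "plasma_only": len(p - c - m),
        "core_margin": len((c & m) - p),
        "core_plasma": len((c & p) - m),
        "margin_plasma": len((m & p) - c),
        "core_margin_plasma": len(c & m & p),
    }
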