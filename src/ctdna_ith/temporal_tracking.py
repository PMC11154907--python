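"""Baseline vs acquired variant tracking across serial plasma timepoints.

Variants present in the resected primary tumour (core or margin) are
*baseline*; variants never seen in either tumour sub-site but present in at
least one post-treatment plasma sample (timepoints B-D, collection day > 0
relative to treatment completion) are *acquired*.  Variants seen only in the
baseline plasma draw (A) receive neither label and are reported separately —
with two-site tumour sampling they cannot be attributed to the tumour or to
acquisition.

Molecular recurrence is called at the earliest post-treatment timepoint with
at least one qualifying variant present (by default restricted to the HNSCC
COSMIC subset, since those are the oncogenic variants worth tracking); the
lead time is the gap to the clinical recurrence day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

from .io_formats import (
    Annotation,
    PatientVariantTable,
    SampleSheet,
    VariantKey,
)
from .somatic_filter import PresenceMatrix
from .spatial_ith import TUMOUR_CLASSES, SpatialClass


class TemporalLabel(str, Enum):
    BASELINE = "BASELINE"
    ACQUIRED = "ACQUIRED"


@dataclass(frozen=True)
class TimepointState:
    timepoint: str
    collection_day: int
    present: bool
    vaf: float  # NaN unless present


@dataclass(frozen=True)
class VariantTrajectory:
    """Presence/VAF of one labelled variant across plasma timepoints A-D."""

    patient_id: str
    variant: VariantKey
    annotation: Annotation
    label: TemporalLabel
    states: tuple[TimepointState, ...] = field(default_factory=tuple)

    @property
    def first_detection_day(self) -> int | None:
        for st in self.states:
            if st.present:
                return st.collection_day
        return None

    @property
    def persisted(self) -> bool:
        """Present at two consecutive sampled timepoints."""
        flags = [st.present for st in self.states]
        return any(a and b for a, b in zip(flags, flags[1:]))

    @property
    def lost(self) -> bool:
        """Present then absent at a later sampled timepoint."""
        flags = [st.present for st in self.states]
        seen = False
        for f in flags:
            if seen and not f:
                return True
            seen = seen or f
        return False

    @property
    def re_emerged(self) -> bool:
        """Present, absent at >=1 intermediate timepoint, then present again."""
        flags = [st.present for st in self.states]
        state = 0  # 0: before first presence, 1: present seen, 2: gap seen
        for f in flags:
            if state == 0 and f:
                state = 1
            elif state == 1 and not f:
                state = 2
            elif state == 2 and f:
                return True
        return False


@dataclass(frozen=True)
class MolecularRecurrenceCall:
    patient_id: str
    detection_day: int | None
    clinical_recurrence_day: int | None

    @property
    def lead_time_days(self) -> int | None:
        if self.detection_day is None or self.clinical_recurrence_day is None:
            return None
        return self.clinical_recurrence_day - self.detection_day


def _post_treatment_plasma(sample_sheet: SampleSheet, patient_id: str):
    return {
        tp: info
        for tp, info in sample_sheet.plasma_samples(patient_id).items()
        if info.collection_day > 0
    }


def label_variants(
    presence: PresenceMatrix,
    classes: Mapping[VariantKey, SpatialClass],
    sample_sheet: SampleSheet,
    strict_acquired: bool = False,
) -> tuple[dict[VariantKey, TemporalLabel], set[VariantKey]]:
    """Label variants BASELINE / ACQUIRED; returns (labels, plasma-A-only set).

    BASELINE: present in core or margin.  ACQUIRED: absent from both tumour
    sub-sites, present in >= 1 post-treatment plasma sample (strict mode
    additionally requires absence from plasma A).  Variants present only in
    plasma A are returned in the second set, unlabelled.
    """
    pid = presence.patient_id
    plasma = sample_sheet.plasma_samples(pid)
    post = _post_treatment_plasma(sample_sheet, pid)
    baseline_plasma = plasma.get("A")

    labels: dict[VariantKey, TemporalLabel] = {}
    plasma_a_only: set[VariantKey] = set()
    for v in presence.variants:
        tumour_present = classes.get(v) in TUMOUR_CLASSES
        in_post = any(presence.present(v, info.sample_name) for info in post.values())
        in_a = baseline_plasma is not None and presence.present(
            v, baseline_plasma.sample_name
        )
        if tumour_present:
            labels[v] = TemporalLabel.BASELINE
        elif in_post and not (strict_acquired and in_a):
            labels[v] = TemporalLabel.ACQUIRED
        elif in_a:
            plasma_a_only.add(v)
    return labels, plasma_a_only


def build_trajectories(
    presence: PresenceMatrix,
    labels: Mapping[VariantKey, TemporalLabel],
    table: PatientVariantTable,
    sample_sheet: SampleSheet,
) -> list[VariantTrajectory]:
    """One A-D trajectory per labelled variant, ordered by collection day."""
    pid = presence.patient_id
    plasma = sample_sheet.plasma_samples(pid)
    out = []
    for v in sorted(labels):
        states = []
        for tp, info in plasma.items():
            pres = presence.present(v, info.sample_name)
            vaf = table.call(v, info.sample_name).vaf if pres else math.nan
            states.append(TimepointState(tp, info.collection_day, pres, vaf))
        out.append(
            VariantTrajectory(
                patient_id=pid,
                variant=v,
                annotation=table.annotation(v),
                label=labels[v],
                states=tuple(states),
            )
        )
    return out


def molecular_recurrence(
    trajectories: list[VariantTrajectory],
    sample_sheet: SampleSheet,
    patient_id: str,
    qualifying: str = "cosmic_subset",
) -> MolecularRecurrenceCall:
    """Earliest post-treatment plasma detection vs clinical recurrence.

    detection_day is the minimum collection day over post-treatment
    timepoints at which >= 1 qualifying (BASELINE or ACQUIRED) variant is
    present; None when no qualifying detection occurs.
    """
    if qualifying not in ("cosmic_subset", "all"):
        raise ValueError(f"unknown qualifying mode {qualifying!r}")
    recurrence_day = sample_sheet.recurrence_day(patient_id)
    detection_day: int | None = None
    for traj in trajectories:
        if traj.patient_id != patient_id:
            continue
        if qualifying == "cosmic_subset" and not traj.annotation.in_hnscc_cosmic_subset:
            continue
        for st in traj.states:
            if st.present and st.collection_day > 0:
                if detection_day is None or st.collection_day < detection_day:
                    detection_day = st.collection_day
    return MolecularRecurrenceCall(
        patient_id=patient_id,
        detection_day=detection_day,
        clinical_recurrence_day=recurrence_day,
    )


def trajectory_frame(trajectories: list[VariantTrajectory]) -> pd.DataFrame:
    """Long-format trajectory table (one row per variant x timepoint)."""
    rows = []
    for t in trajectories:
        for st in t.states:
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "chrom": t.variant.chrom,
                    "pos": t.variant.pos,
                    "ref": t.variant.ref,
                    "alt": t.variant.alt,
                    "gene": t.annotation.gene,
                    "label": t.label.value,
                    "timepoint": st.timepoint,
                    "collection_day": st.collection_day,
                    "present": st.present,
                    "vaf": st.vaf,
                }
            )
    return pd.DataFrame(rows)


def recurrence_frame(calls: list[MolecularRecurrenceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "patient_id": c.patient_id,
                "detection_day": "" if c.detection_day is None else c.detection_day,
                "clinical_recurrence_day": (
                    "" if c.clinical_recurrence_day is None else c.clinical_recurrence_day
                ),
                "lead_time_days": "" if c.lead_time_days is None else c.lead_time_days,
            }
        )
    return pd.DataFrame(rows)
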