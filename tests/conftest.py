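"""Shared fixtures: a compact builder for hand-crafted patient tables."""

from __future__ import annotations

import pytest

from ctdna_ith.io_formats import (
    Annotation,
    PatientVariantTable,
    SampleInfo,
    SampleSheet,
    VariantCall,
    VariantKey,
)

# sample-label -> (role, timepoint, collection day relative to treatment end)
SAMPLE_DEFS = {
    "PBMC": ("PBMC", None, -30),
    "CORE": ("CORE", None, -30),
    "MARGIN": ("MARGIN", None, -30),
    "A": ("PLASMA", "A", -30),
    "B": ("PLASMA", "B", 56),
    "C": ("PLASMA", "C", 118),
    "D": ("PLASMA", "D", 365),
}


def vkey(name: str) -> VariantKey:
    """Deterministic variant key for a short name like 'v3'."""
    idx = int(name.lstrip("v"))
    return VariantKey("chr1", 1000 + idx, "A", "T")


def make_patient(
    calls: dict[str, dict[str, tuple[int, int]]],
    annotations: dict[str, tuple[str, str, bool]] | None = None,
    sample_labels: tuple[str, ...] = ("PBMC", "CORE", "MARGIN", "A"),
    patient_id: str = "P1",
    recurrence_day: int | None = None,
    default_call: tuple[int, int] = (50, 0),
) -> tuple[PatientVariantTable, SampleSheet]:
    """Build a one-patient table + sheet from sparse (depth, alt) entries.

    ``calls`` maps variant names ('v1', ...) to per-sample-label
    (depth, alt_reads); unlisted samples get ``default_call``.
    ``annotations`` maps variant names to (gene, cosmic_id, in_subset).
    """
    infos = [
        SampleInfo(
            patient_id,
            f"{patient_id}_{label}",
            *SAMPLE_DEFS[label][:2],
            collection_day=SAMPLE_DEFS[label][2],
            recurrence_day=recurrence_day,
        )
        for label in sample_labels
    ]
    sheet = SampleSheet(infos)
    variants = [vkey(name) for name in calls]
    table_calls = {}
    for name, per_sample in calls.items():
        for label in sample_labels:
            depth, alt = per_sample.get(label, default_call)
            table_calls[(vkey(name), f"{patient_id}_{label}")] = VariantCall(depth, alt)
    anns = {
        vkey(name): Annotation(gene, cid, flag)
        for name, (gene, cid, flag) in (annotations or {}).items()
    }
    table = PatientVariantTable(
        patient_id=patient_id,
        variants=variants,
        samples=[s.sample_name for s in infos],
        calls=table_calls,
        annotations=anns,
    )
    return table, sheet


@pytest.fixture
def patient_builder():
    return make_patient
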