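"""Baseline plasma vs tumour overlap metrics."""

import math

import pytest

from ctdna_ith.ctdna_concordance import (
    cohort_concordance,
    concordance,
    leave_one_out_means,
    venn_counts,
)
from ctdna_ith.somatic_filter import apply_filter_cascade, build_presence_matrix
from ctdna_ith.spatial_ith import classify_spatial, high_frequency_subset

from conftest import make_patient, vkey

HIGH = (100, 20)   # 20% VAF: tumour-present and high frequency
LOW = (100, 4)     # 4% VAF: present, below the 5% cutoff
ABSENT = (100, 0)


def build(calls, annotations=None, patient_id="P1", **kw):
    table, sheet = make_patient(calls, annotations=annotations,
                                patient_id=patient_id, **kw)
    decisions = apply_filter_cascade(table, sheet)
    presence = build_presence_matrix(table, decisions)
    classes = classify_spatial(presence, sheet)
    hf = high_frequency_subset(table, presence, sheet)
    return table, sheet, presence, classes, hf


def auto_annotations(names):
    return {n: ("TP53", f"COSV{n}", True) for n in names}


def test_worked_set_arithmetic():
    # tumour v1..v10, high-frequency v1..v4, plasma {v1,v2,v3,v11}
    calls = {}
    for i in range(1, 5):
        calls[f"v{i}"] = {"CORE": HIGH, "MARGIN": ABSENT}
    for i in range(5, 11):
        calls[f"v{i}"] = {"CORE": LOW, "MARGIN": ABSENT}
    for i in (1, 2, 3, 11):
        calls.setdefault(f"v{i}", {"CORE": ABSENT, "MARGIN": ABSENT})
        calls[f"v{i}"]["A"] = (500, 10)
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls))
    assert hf == {vkey(f"v{i}") for i in range(1, 5)}
    s = concordance(presence, classes, hf, table, sheet)
    assert s.n_tumour == 10 and s.n_plasma == 4
    assert s.detection_rate_all == pytest.approx(0.3)
    assert s.detection_rate_highfreq == pytest.approx(0.75)
    assert s.plasma_only_fraction == pytest.approx(0.25)
    assert s.exclusivity_among_detected == pytest.approx(1.0)  # all core-only
    # set identity: n_plasma = detected + plasma-only
    assert s.n_plasma == round(s.detection_rate_all * s.n_tumour) + round(
        s.plasma_only_fraction * s.n_plasma
    )


def test_equal_and_disjoint_sets():
    calls = {f"v{i}": {"CORE": HIGH, "A": (500, 10)} for i in range(1, 4)}
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls))
    s = concordance(presence, classes, hf, table, sheet)
    assert s.detection_rate_all == 1.0 and s.plasma_only_fraction == 0.0

    calls = {"v1": {"CORE": HIGH}, "v2": {"CORE": ABSENT, "MARGIN": ABSENT, "A": (500, 10)}}
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls))
    s = concordance(presence, classes, hf, table, sheet)
    assert s.detection_rate_all == 0.0 and s.plasma_only_fraction == 1.0


def test_undefined_rates_are_nan_not_zero():
    calls = {"v1": {"CORE": ABSENT, "MARGIN": ABSENT, "A": ABSENT}}
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls))
    s = concordance(presence, classes, hf, table, sheet)
    assert math.isnan(s.detection_rate_all)
    assert math.isnan(s.plasma_only_fraction)


def test_panel_restriction_excludes_off_panel_genes():
    anns = {"v1": ("TP53", "COSV1", True), "v2": ("HRAS", "COSV2", True)}
    calls = {"v1": {"CORE": HIGH, "A": (500, 10)}, "v2": {"CORE": HIGH, "A": (500, 10)}}
    table, sheet, presence, classes, hf = build(calls, anns)
    s = concordance(presence, classes, hf, table, sheet, panel_genes=["TP53"])
    assert s.n_tumour == 1  # HRAS outside the plasma panel
    s_all = concordance(presence, classes, hf, table, sheet, panel_genes=None)
    assert s_all.n_tumour == 2


def test_patient_without_baseline_plasma_is_skipped():
    table, sheet = make_patient({"v1": {"CORE": HIGH}},
                                sample_labels=("PBMC", "CORE", "MARGIN"))
    decisions = apply_filter_cascade(table, sheet)
    presence = build_presence_matrix(table, decisions)
    classes = classify_spatial(presence, sheet)
    assert concordance(presence, classes, set(), table, sheet) is None


def make_summary(pid, rate):
    calls = {"v1": {"CORE": HIGH, "A": (500, 10) if rate else ABSENT}}
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls), patient_id=pid)
    return concordance(presence, classes, hf, table, sheet)


def test_cohort_mean_range_and_leave_one_out():
    # rates 1, 1, 0 across three patients
    summaries = [make_summary("P1", 1), make_summary("P2", 1), make_summary("P3", 0)]
    c = cohort_concordance(summaries)
    assert c.detection_rate_all == pytest.approx(2 / 3)
    assert (c.rate_all_min, c.rate_all_max) == (0.0, 1.0)
    loo = leave_one_out_means(summaries, "detection_rate_all")
    assert loo == {"P1": pytest.approx(0.5), "P2": pytest.approx(0.5),
                   "P3": pytest.approx(1.0)}
    single = cohort_concordance([summaries[0]])
    assert single.detection_rate_all == 1.0
    assert single.rate_all_min == single.rate_all_max == 1.0


def test_venn_counts_partition_presence():
    calls = {
        "v1": {"CORE": HIGH, "MARGIN": HIGH, "A": (500, 10)},
        "v2": {"CORE": HIGH},
        "v3": {"MARGIN": HIGH, "A": (500, 10)},
        "v4": {"CORE": ABSENT, "MARGIN": ABSENT, "A": (500, 10)},
    }
    table, sheet, presence, classes, hf = build(calls, auto_annotations(calls))
    counts = venn_counts(presence, sheet, table)
    assert counts["core_margin_plasma"] == 1
    assert counts["core_only"] == 1
    assert counts["margin_plasma"] == 1
    assert counts["plasma_only"] == 1
    assert sum(counts.values()) == 4
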