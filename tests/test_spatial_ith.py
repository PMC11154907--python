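"""Sub-site exclusivity classification and heterogeneity summaries."""

import math

import pytest
from scipy import stats

from ctdna_ith.somatic_filter import (
    FilterThresholds,
    apply_filter_cascade,
    build_presence_matrix,
)
from ctdna_ith.spatial_ith import (
    SpatialClass,
    classify_spatial,
    cohort_heterogeneity,
    compare_exclusivity,
    gene_level_summary,
    heterogeneity_summary,
    high_frequency_subset,
)

from conftest import make_patient, vkey

PRESENT = (100, 20)  # VAF 0.2, comfortably detectable
ABSENT = (100, 0)


def run_patient(calls, annotations=None, thresholds=FilterThresholds()):
    table, sheet = make_patient(calls, annotations=annotations)
    decisions = apply_filter_cascade(table, sheet, thresholds)
    presence = build_presence_matrix(table, decisions, thresholds)
    return table, sheet, presence


def test_classification_examples():
    table, sheet, presence = run_patient(
        {
            "v1": {"CORE": PRESENT, "MARGIN": ABSENT},
            "v2": {"CORE": PRESENT, "MARGIN": PRESENT},
            "v3": {"CORE": ABSENT, "MARGIN": PRESENT},
            "v4": {"CORE": ABSENT, "MARGIN": ABSENT, "A": PRESENT},
        }
    )
    classes = classify_spatial(presence, sheet)
    assert classes[vkey("v1")] is SpatialClass.CORE_ONLY
    assert classes[vkey("v2")] is SpatialClass.SHARED
    assert classes[vkey("v3")] is SpatialClass.MARGIN_ONLY
    assert classes[vkey("v4")] is SpatialClass.NOT_IN_TUMOUR


def test_missing_subsite_is_error():
    table, sheet = make_patient({"v1": {}}, sample_labels=("PBMC", "CORE", "A"))
    decisions = apply_filter_cascade(table, sheet)
    presence = build_presence_matrix(table, decisions)
    with pytest.raises(ValueError, match="P1"):
        classify_spatial(presence, sheet)


def _classes(n_core, n_margin, n_shared, n_out=0):
    out = {}
    i = 0
    for cls, n in [
        (SpatialClass.CORE_ONLY, n_core),
        (SpatialClass.MARGIN_ONLY, n_margin),
        (SpatialClass.SHARED, n_shared),
        (SpatialClass.NOT_IN_TUMOUR, n_out),
    ]:
        for _ in range(n):
            out[vkey(f"v{i}")] = cls
            i += 1
    return out


def test_heterogeneity_arithmetic():
    s = heterogeneity_summary(_classes(4, 3, 3))
    assert s.heterogeneity_rate == pytest.approx(0.7)
    assert s.prop_core_only + s.prop_margin_only + s.prop_shared == pytest.approx(1.0)
    assert heterogeneity_summary(_classes(0, 0, 5)).heterogeneity_rate == 0.0


def test_plasma_only_variants_excluded_from_denominator():
    s = heterogeneity_summary(_classes(1, 0, 1, n_out=8))
    assert s.n_variants == 2
    assert s.heterogeneity_rate == pytest.approx(0.5)


def test_zero_variant_summary_is_undefined_not_zero():
    s = heterogeneity_summary(_classes(0, 0, 0, n_out=3))
    assert not s.defined
    assert math.isnan(s.heterogeneity_rate)


def test_core_margin_symmetry():
    a = heterogeneity_summary(_classes(4, 1, 5))
    b = heterogeneity_summary(_classes(1, 4, 5))
    assert a.prop_core_only == b.prop_margin_only
    assert a.heterogeneity_rate == b.heterogeneity_rate


def test_cohort_mean_is_unweighted_over_patients():
    # patient 1: 10 variants all exclusive; patient 2: 2 variants, half shared
    s1 = heterogeneity_summary(_classes(10, 0, 0))
    s2 = heterogeneity_summary(_classes(1, 0, 1))
    c = cohort_heterogeneity([s1, s2])
    assert c.heterogeneity_rate == pytest.approx((1.0 + 0.5) / 2)  # not 11/12
    assert (c.rate_min, c.rate_max) == (0.5, 1.0)


def test_gene_level_means_match_hand_computation():
    anns = {
        "v1": ("TP53", "C1", True),
        "v2": ("TP53", "C2", True),
        "v3": ("FAT1", "C3", True),
    }
    # P1: TP53 has one exclusive + one shared variant; FAT1 one exclusive
    t1, s1, p1 = run_patient(
        {
            "v1": {"CORE": PRESENT, "MARGIN": ABSENT},
            "v2": {"CORE": PRESENT, "MARGIN": PRESENT},
            "v3": {"CORE": ABSENT, "MARGIN": PRESENT},
        },
        annotations=anns,
    )
    # P2: only a shared TP53 variant
    t2, s2, p2 = run_patient({"v1": {"CORE": PRESENT, "MARGIN": PRESENT}},
                             annotations={"v1": ("TP53", "C1", True)})
    classes = {"P1": classify_spatial(p1, s1), "P2": classify_spatial(p2, s2)}
    annotations = {"P1": t1.annotations, "P2": t2.annotations}
    df = gene_level_summary(classes, annotations, ["TP53", "FAT1", "PTEN"])
    tp53 = df.set_index("gene").loc["TP53"]
    assert tp53["n_patients"] == 2
    assert tp53["mean_exclusivity"] == pytest.approx((0.5 + 0.0) / 2)
    fat1 = df.set_index("gene").loc["FAT1"]
    assert fat1["n_patients"] == 1 and fat1["mean_exclusivity"] == 1.0
    pten = df.set_index("gene").loc["PTEN"]
    assert pten["n_patients"] == 0 and math.isnan(pten["mean_exclusivity"])


def test_high_frequency_subset_strict_cutoff():
    table, sheet, presence = run_patient(
        {
            "v1": {"CORE": (100, 6), "MARGIN": ABSENT},   # core vaf 0.06 > 5%
            "v2": {"CORE": (100, 5), "MARGIN": (100, 4)}, # exactly 5%: excluded
            "v3": {"CORE": (100, 2), "MARGIN": (100, 7)}, # margin 0.07
            "v4": {"CORE": ABSENT, "MARGIN": ABSENT, "A": (100, 30)},  # plasma only
        }
    )
    hf = high_frequency_subset(table, presence, sheet)
    assert hf == {vkey("v1"), vkey("v3")}
    # consistency: subset of tumour-present variants
    classes = classify_spatial(presence, sheet)
    assert all(classes[v] is not SpatialClass.NOT_IN_TUMOUR for v in hf)


def test_t_test_examples_and_closed_form():
    t, p = compare_exclusivity([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    _, p = compare_exclusivity([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
    assert p < 0.001
    # textbook pooled-variance computation
    a, b = [0.1, 0.3, 0.5, 0.2], [0.4, 0.6, 0.7]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sp2 = (sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)) / (na + nb - 2)
    t_hand = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
    t_got, p_got = compare_exclusivity(a, b)
    assert t_got == pytest.approx(t_hand)
    assert p_got == pytest.approx(p_hand)
    with pytest.raises(ValueError):
        compare_exclusivity([0.5], [0.1, 0.2])
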