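"""Somatic selection cascade: rule order, rescue, presence floor, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_ith.somatic_filter import (
    FilterOutcome,
    FilterThresholds,
    apply_filter_cascade,
    build_presence_matrix,
)

from conftest import make_patient, vkey

T = FilterThresholds()


def cascade_oracle(pbmc, others, cosmic, t=T):
    """Independent rule-by-rule evaluator (straight transcription of the rules).

    pbmc and each element of others are (depth, alt_reads) pairs; others are
    the tumour/plasma samples.
    """
    p_depth, p_alt = pbmc
    germline = p_depth >= t.germline_min_depth and p_alt / p_depth > t.germline_af_max
    has_support = any(a >= t.min_supporting_reads for _, a in others)
    lowcov_rescue = any(
        d > 0 and a / d > t.lowcov_af_min and a >= t.lowcov_min_reads for d, a in others
    )
    if germline:
        out = "REMOVED_GERMLINE"
    elif not has_support:
        out = "REMOVED_LOW_SUPPORT"
    elif p_depth < t.germline_min_depth and not lowcov_rescue:
        out = "REMOVED_LOWCOV_PBMC"
    else:
        out = "RETAINED"
    if out != "RETAINED" and cosmic:
        out = "RESCUED_COSMIC"
    return out


def run_one(pbmc, core, margin=(50, 0), cosmic=False, thresholds=T):
    ann = {"v1": ("TP53", "COSV1", True)} if cosmic else None
    table, sheet = make_patient(
        {"v1": {"PBMC": pbmc, "CORE": core, "MARGIN": margin}}, annotations=ann
    )
    return apply_filter_cascade(table, sheet, thresholds)[vkey("v1")]


@pytest.mark.parametrize(
    "pbmc,core,cosmic,expected",
    [
        # well-covered PBMC at 15% VAF: germline removal
        ((30, 5), (50, 20), False, FilterOutcome.REMOVED_GERMLINE),
        # same but a known HNSCC COSMIC variant: rescued
        ((30, 5), (50, 20), True, FilterOutcome.RESCUED_COSMIC),
        # thin PBMC but a strong tumour signal (25% VAF, 12 reads): kept
        ((10, 0), (48, 12), False, FilterOutcome.RETAINED),
        # thin PBMC, tumour 25% VAF on only 6 reads: untestable germline
        ((10, 0), (24, 6), False, FilterOutcome.REMOVED_LOWCOV_PBMC),
        # no sample reaches 4 supporting reads
        ((30, 0), (50, 3), False, FilterOutcome.REMOVED_LOW_SUPPORT),
    ],
)
def test_cascade_examples(pbmc, core, cosmic, expected):
    assert run_one(pbmc, core, cosmic=cosmic).outcome == expected


def test_boundary_comparisons_follow_wording():
    # >10% strict: exactly 10% PBMC VAF is not germline
    assert run_one((30, 3), (50, 20)).outcome == FilterOutcome.RETAINED
    # >=20x inclusive: depth exactly 20 counts as adequate germline coverage
    assert run_one((20, 2), (50, 20)).outcome == FilterOutcome.RETAINED  # vaf 10%
    assert run_one((20, 4), (50, 20)).outcome == FilterOutcome.REMOVED_GERMLINE
    # 4-or-more inclusive
    assert run_one((30, 0), (50, 4)).outcome == FilterOutcome.RETAINED


def test_missing_pbmc_is_error():
    table, sheet = make_patient({"v1": {}}, sample_labels=("PBMC", "CORE"))
    table.samples = [s for s in table.samples if not s.endswith("PBMC")]
    table.variants = []
    with pytest.raises(ValueError, match="PBMC"):
        apply_filter_cascade(table, sheet)


def _random_records(n, seed):
    """Records spanning every rule boundary: depth near 20, VAF near 10/20%,
    reads near 4/10."""
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        p_depth = int(rng.integers(1, 41))
        p_alt = int(rng.integers(0, p_depth + 1))
        others = []
        for _ in range(int(rng.integers(1, 4))):
            d = int(rng.integers(1, 61))
            # mixture concentrating alt reads near the 4/10 boundaries
            if rng.random() < 0.5:
                a = int(rng.integers(0, 13))
            else:
                a = int(rng.integers(0, d + 1))
            others.append((d, min(a, d)))
        records.append((p_depth, p_alt, others, bool(rng.random() < 0.3)))
    return records


def build_cohort_table(records):
    calls = {}
    anns = {}
    for i, (p_depth, p_alt, others, cosmic) in enumerate(records):
        name = f"v{i}"
        row = {"PBMC": (p_depth, p_alt)}
        for j, (d, a) in enumerate(others):
            row[("CORE", "MARGIN", "A")[j]] = (d, a)
        calls[name] = row
        if cosmic:
            anns[name] = ("TP53", f"COSV{i}", True)
    return make_patient(
        calls, annotations=anns, sample_labels=("PBMC", "CORE", "MARGIN", "A"),
        default_call=(0, 0),
    )


def test_outcomes_match_brute_force_oracle():
    records = _random_records(2000, seed=11)
    table, sheet = build_cohort_table(records)
    decisions = apply_filter_cascade(table, sheet)
    for i, (p_depth, p_alt, others, cosmic) in enumerate(records):
        padded = others + [(0, 0)] * (3 - len(others))
        expected = cascade_oracle((p_depth, p_alt), padded, cosmic)
        assert decisions[vkey(str(i))].outcome.value == expected, f"record {i}"


def test_partition_and_idempotence():
    records = _random_records(500, seed=3)
    table, sheet = build_cohort_table(records)
    decisions = apply_filter_cascade(table, sheet)
    assert len(decisions) == len(table.variants)
    kept = [v for v, d in decisions.items() if d.kept]
    # rerunning on the kept subset changes no outcome
    table.variants = kept
    again = apply_filter_cascade(table, sheet)
    for v in kept:
        assert again[v].outcome == decisions[v].outcome


@given(st.integers(0, 30).map(lambda x: x / 100))
@settings(max_examples=20, deadline=None)
def test_raising_germline_cutoff_never_shrinks_kept_set(af_max):
    records = _random_records(200, seed=7)
    table, sheet = build_cohort_table(records)
    loose = FilterThresholds(germline_af_max=af_max, lowcov_af_min=0.31)
    tight = FilterThresholds(germline_af_max=0.0, lowcov_af_min=0.31)
    kept_loose = {v for v, d in apply_filter_cascade(table, sheet, loose).items() if d.kept}
    kept_tight = {v for v, d in apply_filter_cascade(table, sheet, tight).items() if d.kept}
    assert kept_tight <= kept_loose


def test_presence_floor_boundaries():
    table, sheet = make_patient(
        {
            "v1": {"PBMC": (30, 0), "CORE": (1000, 1), "MARGIN": (50, 10)},
            "v2": {"PBMC": (30, 0), "CORE": (2000, 1), "MARGIN": (50, 10)},
            "v3": {"PBMC": (30, 10), "CORE": (50, 25), "MARGIN": (50, 10)},
        }
    )
    decisions = apply_filter_cascade(table, sheet)
    presence = build_presence_matrix(table, decisions)
    core = "P1_CORE"
    assert presence.present(vkey("v1"), core)  # vaf exactly 0.001: inclusive
    assert not presence.present(vkey("v2"), core)  # vaf 0.0005: below floor
    assert not presence.present(vkey("v3"), core)  # germline-removed variant


def test_raising_presence_floor_never_grows_present_sets():
    records = _random_records(300, seed=5)
    table, sheet = build_cohort_table(records)
    decisions = apply_filter_cascade(table, sheet)
    lo = build_presence_matrix(table, decisions, FilterThresholds(final_vaf_min=0.001))
    hi = build_presence_matrix(table, decisions, FilterThresholds(final_vaf_min=0.05))
    for s in table.samples:
        assert hi.present_set(s) <= lo.present_set(s)


def test_threshold_invariants_enforced():
    with pytest.raises(ValueError):
        FilterThresholds(germline_af_max=1.5)
    with pytest.raises(ValueError):
        FilterThresholds(germline_af_max=0.25, lowcov_af_min=0.2)


def test_restore_removed_with_support_mode():
    # alternative reading: a germline-removed variant with >=4 supporting
    # reads elsewhere is restored
    alt = FilterThresholds(restore_removed_with_support=True)
    assert run_one((30, 5), (50, 20), thresholds=alt).outcome == FilterOutcome.RETAINED
    assert run_one((30, 5), (50, 3), thresholds=alt).outcome == FilterOutcome.REMOVED_GERMLINE
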