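"""Per-patient somatic variant selection with germline/CHIP subtraction.

The cascade mirrors tumour-informed ctDNA practice: candidate variants are
called jointly across all of a patient's samples, then filtered against the
matched PBMC germline control, with a rescue path for known HNSCC COSMIC
variants and a universal 0.1% VAF presence floor.

Rules are evaluated in a fixed order for every variant:

R1  germline removal      PBMC depth >= 20 and PBMC VAF > 10%  -> removed
R2  minimum evidence      no non-PBMC sample with >= 4 alt reads -> removed
R3  untestable germline   PBMC depth < 20 and no non-PBMC sample with
                          VAF > 20% and >= 10 alt reads          -> removed
R4  COSMIC rescue         any removed variant in the HNSCC COSMIC subset
                          is restored to candidacy

Comparisons follow the stated thresholds literally: percentage cut-offs are
strict (>), read-count and coverage cut-offs are inclusive (>=), and the
final 0.1% VAF floor is inclusive.  R4 restores candidacy only — a rescued
variant must still clear the per-sample presence floor.  PBMC reads never
count as supporting evidence; rescuing on germline reads would defeat the
subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .io_formats import ROLE_PBMC, PatientVariantTable, SampleSheet, VariantKey


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable cut-offs of the selection cascade (defaults = study values).

    germline_af_max      PBMC VAF above which a well-covered site is germline.
    germline_min_depth   PBMC coverage needed to trust the germline call.
    min_supporting_reads minimum alt reads in >= 1 tumour/plasma sample.
    lowcov_af_min /      rescue condition when PBMC coverage is inadequate:
    lowcov_min_reads     some tumour/plasma sample with VAF > 20% and >= 10 reads.
    final_vaf_min        per-sample presence floor (0.1%), tumour and plasma.
    high_freq_vaf        'high frequency' (inferred-clonal) tumour VAF cut-off.
    restore_removed_with_support
                         alternative reading of the evidence rule: germline-
                         removed variants are restored when some non-PBMC
                         sample has >= min_supporting_reads alt reads.  Off by
                         default; the default reading treats R2 as a minimum
                         evidence requirement on the kept set.
    """

    germline_af_max: float = 0.10
    germline_min_depth: int = 20
    min_supporting_reads: int = 4
    lowcov_af_min: float = 0.20
    lowcov_min_reads: int = 10
    final_vaf_min: float = 0.001
    high_freq_vaf: float = 0.05
    restore_removed_with_support: bool = False

    def __post_init__(self) -> None:
        for name in ("germline_af_max", "lowcov_af_min", "final_vaf_min", "high_freq_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lowcov_af_min <= self.germline_af_max:
            raise ValueError("lowcov_af_min must exceed germline_af_max")
        for name in ("germline_min_depth", "min_supporting_reads", "lowcov_min_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class FilterOutcome(str, Enum):
    RETAINED = "RETAINED"
    REMOVED_GERMLINE = "REMOVED_GERMLINE"
    REMOVED_LOW_SUPPORT = "REMOVED_LOW_SUPPORT"
    REMOVED_LOWCOV_PBMC = "REMOVED_LOWCOV_PBMC"
    RESCUED_COSMIC = "RESCUED_COSMIC"


REMOVAL_OUTCOMES = frozenset(
    {
        FilterOutcome.REMOVED_GERMLINE,
        FilterOutcome.REMOVED_LOW_SUPPORT,
        FilterOutcome.REMOVED_LOWCOV_PBMC,
    }
)
KEPT_OUTCOMES = frozenset({FilterOutcome.RETAINED, FilterOutcome.RESCUED_COSMIC})


@dataclass(frozen=True)
class FilterDecision:
    """Audit trail of one variant through the cascade."""

    variant: VariantKey
    outcome: FilterOutcome
    rule_trace: tuple[tuple[str, bool], ...] = field(default_factory=tuple)

    @property
    def kept(self) -> bool:
        return self.outcome in KEPT_OUTCOMES


def apply_filter_cascade(
    table: PatientVariantTable,
    sample_sheet: SampleSheet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> dict[VariantKey, FilterDecision]:
    """Run the R1-R4 cascade on every variant of one patient's table."""
    pbmc = sample_sheet.pbmc_sample(table.patient_id)
    if pbmc not in table.samples:
        raise ValueError(
            f"patient {table.patient_id}: PBMC sample {pbmc!r} missing from table"
        )
    others = [s for s in table.samples if s != pbmc]
    t = thresholds

    decisions: dict[VariantKey, FilterDecision] = {}
    for v in table.variants:
        g = table.call(v, pbmc)
        non_pbmc = [table.call(v, s) for s in others]
        trace: list[tuple[str, bool]] = []

        r1 = g.depth >= t.germline_min_depth and (
            not math.isnan(g.vaf) and g.vaf > t.germline_af_max
        )
        trace.append(("R1_germline", r1))
        outcome: FilterOutcome | None = None
        if r1:
            outcome = FilterOutcome.REMOVED_GERMLINE
            if t.restore_removed_with_support and any(
                c.alt_reads >= t.min_supporting_reads for c in non_pbmc
            ):
                trace.append(("R1_support_restore", True))
                outcome = None
        if outcome is None:
            r2 = not any(c.alt_reads >= t.min_supporting_reads for c in non_pbmc)
            trace.append(("R2_low_support", r2))
            if r2 and not r1:
                outcome = FilterOutcome.REMOVED_LOW_SUPPORT
        if outcome is None:
            lowcov_rescued = any(
                not math.isnan(c.vaf)
                and c.vaf > t.lowcov_af_min
                and c.alt_reads >= t.lowcov_min_reads
                for c in non_pbmc
            )
            r3 = g.depth < t.germline_min_depth and not lowcov_rescued
            trace.append(("R3_lowcov_pbmc", r3))
            if r3:
                outcome = FilterOutcome.REMOVED_LOWCOV_PBMC
        if outcome is None:
            outcome = FilterOutcome.RETAINED
        elif table.annotation(v).in_hnscc_cosmic_subset:
            trace.append(("R4_cosmic_rescue", True))
            outcome = FilterOutcome.RESCUED_COSMIC
        decisions[v] = FilterDecision(variant=v, outcome=outcome, rule_trace=tuple(trace))
    return decisions


class PresenceMatrix:
    """Per-(variant, sample) presence after filtering and the 0.1% VAF floor.

    A variant is present in a sample iff its cascade outcome kept it, the
    sample shows at least one alt read at non-zero depth, and the sample VAF
    meets the presence floor (inclusive).
    """

    def __init__(self, patient_id: str, present: dict[tuple[VariantKey, str], bool],
                 variants: list[VariantKey], samples: list[str]):
        self.patient_id = patient_id
        self._present = present
        self.variants = variants
        self.samples = samples

    def present(self, variant: VariantKey, sample: str) -> bool:
        return self._present.get((variant, sample), False)

    def present_in_any(self, variant: VariantKey, samples: list[str]) -> bool:
        return any(self.present(variant, s) for s in samples)

    def present_set(self, sample: str) -> set[VariantKey]:
        return {v for v in self.variants if self.present(v, sample)}


def build_presence_matrix(
    table: PatientVariantTable,
    decisions: dict[VariantKey, FilterDecision],
    thresholds: FilterThresholds = FilterThresholds(),
) -> PresenceMatrix:
    """Apply the per-sample presence floor to the kept variants."""
    missing = [v for v in table.variants if v not in decisions]
    if missing:
        raise ValueError(f"decisions missing for {len(missing)} variants")
    present: dict[tuple[VariantKey, str], bool] = {}
    for v in table.variants:
        kept = decisions[v].kept
        for s in table.samples:
            c = table.call(v, s)
            present[(v, s)] = (
                kept
                and c.depth >= 1
                and c.alt_reads >= 1
                and c.vaf >= thresholds.final_vaf_min
            )
    return PresenceMatrix(table.patient_id, present, list(table.variants), list(table.samples))


def filter_trace_frame(table: PatientVariantTable, decisions, sample_sheet: SampleSheet):
    """Per-variant audit table (TSV-ready) of the cascade for one patient."""
    import pandas as pd

    pbmc = sample_sheet.pbmc_sample(table.patient_id)
    others = [s for s in table.samples if s != pbmc]
    rows = []
    for v in table.sorted_variants():
        d = decisions[v]
        ann = table.annotation(v)
        g = table.call(v, pbmc)
        best_reads = max((table.call(v, s).alt_reads for s in others), default=0)
        vafs = [table.call(v, s).vaf for s in others]
        vafs = [x for x in vafs if not math.isnan(x)]
        rows.append(
            {
                "patient_id": table.patient_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": ann.gene,
                "cosmic_id": ann.cosmic_id,
                "outcome": d.outcome.value,
                "fired_rules": ";".join(rid for rid, hit in d.rule_trace if hit),
                "pbmc_depth": g.depth,
                "pbmc_vaf": g.vaf,
                "max_non_pbmc_alt_reads": best_reads,
                "max_non_pbmc_vaf": max(vafs, default=math.nan),
            }
        )
    return pd.DataFrame(rows)
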