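"""Forward simulator for multi-region tumour + serial plasma cohorts.

The simulator generates cohorts with exactly the structure the analysis
assumes, so that every pipeline stage can be verified against known truth:

* a truncal clone (cancer-cell fraction 1) carried by both tumour sub-sites,
  plus core-private and margin-private subclones with CCFs drawn uniformly;
* germline heterozygous/homozygous variants (allele fraction 0.5 / 1.0 in
  every sample including PBMC) and CHIP variants (low allele fraction in
  PBMC and plasma only), exercising the germline/CHIP subtraction path;
* read sampling with Poisson depths (defaults 59x tumour/PBMC, 84x plasma)
  and Binomial alt-read counts — the minimal model under which VAF
  thresholds have calibratable sampling error;
* linear plasma shedding: baseline plasma allele fraction of a somatic
  variant is 0.5 x shed_fraction x mean sub-site CCF;
* post-treatment dynamics: non-resistant clones vanish from plasma after
  treatment, a resistant clone follows per-timepoint regrowth multipliers
  (supporting dormancy-then-re-emergence), and acquired variants appear
  from a configurable onset timepoint.

Acquired variants are emitted with an HNSCC-subset COSMIC ID: they model
the oncogenic panel variants worth tracking post-treatment, and COSMIC
membership is what makes a tumour-absent variant survive the somatic
filter's evidence rules.

Variant positions are placed at unique coordinates inside nominal per-gene
intervals; no reference genome or sequence context is involved.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import panels
from .io_formats import (
    ROLE_CORE,
    ROLE_MARGIN,
    ROLE_PBMC,
    ROLE_PLASMA,
    Annotation,
    PatientVariantTable,
    SampleInfo,
    SampleSheet,
    VariantCall,
    VariantKey,
    write_sample_sheet,
)

BASES = ("A", "C", "G", "T")

CLASS_GERMLINE = "GERMLINE"
CLASS_CHIP = "CHIP"
CLASS_TRUNCAL = "SOMATIC_TRUNCAL"
CLASS_CORE_PRIVATE = "SOMATIC_CORE_PRIVATE"
CLASS_MARGIN_PRIVATE = "SOMATIC_MARGIN_PRIVATE"
CLASS_ACQUIRED = "ACQUIRED"

SOMATIC_CLASSES = (CLASS_TRUNCAL, CLASS_CORE_PRIVATE, CLASS_MARGIN_PRIVATE)


@dataclass(frozen=True)
class RecurrenceScenario:
    """Post-treatment plasma dynamics for a recurring patient.

    The resistant clone is the truncal clone (innate resistance): its plasma
    allele fraction at timepoints B-D is the baseline plasma fraction scaled
    by ``regrowth_multipliers``.  Acquired variants appear from
    ``acquired_onset_timepoint`` at allele fractions drawn uniformly from
    ``acquired_vaf_range``.  Days are relative to treatment completion.
    """

    resistant_clone: bool = True
    regrowth_multipliers: tuple[float, float, float] = (1.0, 2.0, 4.0)  # B, C, D
    n_acquired_variants: int = 3
    acquired_onset_timepoint: str = "B"
    acquired_vaf_range: tuple[float, float] = (0.01, 0.10)
    recurrence_day: int = 102
    plasma_days: tuple[int, int, int] = (56, 118, 365)  # B, C, D


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Depth defaults follow the sequencing design (59x tumour, 84x plasma);
    the somatic variant counts default to a site-exclusive fraction of
    26/30 ~ 0.87, the heterogeneity regime of a two-site HNSCC cohort.
    Purity 0.6 and shed_fraction 0.05 are conventional placeholder values,
    not study-derived estimates.
    """

    n_patients: int = 9
    gene_panel: tuple[str, ...] | None = None  # default: 19-gene TCGA panel
    n_truncal_variants: int = 4
    n_core_private: int = 13
    n_margin_private: int = 13
    ccf_min: float = 0.3
    ccf_max: float = 0.9
    tumour_purity: float = 0.6
    mean_depth_tumour: float = 59.0
    mean_depth_plasma: float = 84.0
    mean_depth_pbmc: float = 59.0
    shed_fraction: float = 0.05
    n_germline_per_patient: int = 30
    n_chip_per_patient: int = 3
    chip_vaf_range: tuple[float, float] = (0.01, 0.10)
    cosmic_fraction: float = 0.6
    baseline_day: int = -30  # tumour/PBMC/plasma-A collection, pre-treatment
    recurrence: RecurrenceScenario | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumour_purity", "shed_fraction", "cosmic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumour_purity == 0.0:
            raise ValueError("tumour_purity must be > 0")
        for name in ("mean_depth_tumour", "mean_depth_plasma", "mean_depth_pbmc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ccf_min <= self.ccf_max <= 1.0:
            raise ValueError("need 0 <= ccf_min <= ccf_max <= 1")

    def panel(self) -> tuple[str, ...]:
        return self.gene_panel or tuple(panels.tcga_hnscc_genes())

    @property
    def exclusive_fraction(self) -> float:
        """Configured true site-exclusivity among somatic tumour variants."""
        n_priv = self.n_core_private + self.n_margin_private
        total = n_priv + self.n_truncal_variants
        return n_priv / total if total else math.nan


@dataclass
class SimVariant:
    """One simulated variant: truth plus sampled read counts per sample."""

    key: VariantKey
    gene: str
    cosmic_id: str
    in_hnscc_cosmic_subset: bool
    sim_class: str
    true_vaf: dict[str, float]  # sample name -> expected allele fraction
    calls: dict[str, VariantCall] = field(default_factory=dict)


@dataclass
class PatientSim:
    patient_id: str
    samples: list[SampleInfo]
    variants: list[SimVariant]

    def sample_names(self) -> list[str]:
        return [s.sample_name for s in self.samples]

    def to_table(self) -> PatientVariantTable:
        calls = {}
        for sv in self.variants:
            for name in self.sample_names():
                calls[(sv.key, name)] = sv.calls[name]
        annotations = {
            sv.key: Annotation(sv.gene, sv.cosmic_id, sv.in_hnscc_cosmic_subset)
            for sv in self.variants
            if sv.gene or sv.cosmic_id
        }
        return PatientVariantTable(
            patient_id=self.patient_id,
            variants=[sv.key for sv in self.variants],
            samples=self.sample_names(),
            calls=calls,
            annotations=annotations,
        )


@dataclass
class CohortSim:
    config: SimConfig
    patients: list[PatientSim]

    def sample_sheet(self) -> SampleSheet:
        return SampleSheet([s for p in self.patients for s in p.samples])

    def tables(self) -> dict[str, PatientVariantTable]:
        return {p.patient_id: p.to_table() for p in self.patients}

    def cosmic_subset(self) -> set[str]:
        return {
            sv.cosmic_id
            for p in self.patients
            for sv in p.variants
            if sv.in_hnscc_cosmic_subset
        }

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            roles = {s.sample_name: s for s in p.samples}
            for sv in p.variants:
                row = {
                    "patient_id": p.patient_id,
                    "chrom": sv.key.chrom,
                    "pos": sv.key.pos,
                    "ref": sv.key.ref,
                    "alt": sv.key.alt,
                    "gene": sv.gene,
                    "cosmic_id": sv.cosmic_id,
                    "in_hnscc_cosmic_subset": sv.in_hnscc_cosmic_subset,
                    "sim_class": sv.sim_class,
                }
                for name, info in roles.items():
                    label = info.role if info.role != ROLE_PLASMA else f"PLASMA_{info.timepoint}"
                    row[f"true_vaf_{label}"] = sv.true_vaf.get(name, 0.0)
                rows.append(row)
        return pd.DataFrame(rows)


def _draw_key(
    rng: np.random.Generator,
    gene: str,
    intervals: dict[str, tuple[str, int, int]],
    used: set[tuple[str, int]],
) -> VariantKey:
    chrom, start, end = intervals[gene]
    while True:
        pos = int(rng.integers(start, end))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    ref = BASES[rng.integers(0, 4)]
    alt = BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = BASES[rng.integers(0, 4)]
    return VariantKey(chrom, pos, ref, alt)


def _sample_call(rng: np.random.Generator, mean_depth: float, true_vaf: float) -> VariantCall:
    depth = int(rng.poisson(mean_depth))
    p = min(max(true_vaf, 0.0), 1.0)
    alt = int(rng.binomial(depth, p)) if depth > 0 else 0
    return VariantCall(depth=depth, alt_reads=alt)


def simulate_patient(
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
    cosmic_counter: list[int],
) -> PatientSim:
    """Simulate one patient's baseline samples (PBMC, core, margin, plasma A).

    Expected allele fractions: a somatic variant in a sub-site has
    0.5 x purity x CCF; baseline plasma has 0.5 x shed_fraction x mean
    sub-site CCF; germline variants are 0.5 or 1.0 everywhere; CHIP variants
    share one low fraction between PBMC and plasma.
    """
    panel = config.panel()
    iv = panels.gene_intervals()
    intervals = {
        r.gene: (r.chrom, int(r.start), int(r.end)) for r in iv.itertuples(index=False)
    }
    missing = [g for g in panel if g not in intervals]
    if missing:
        raise ValueError(f"no interval for panel genes: {missing}")

    day = config.baseline_day
    samples = [
        SampleInfo(patient_id, f"{patient_id}_PBMC", ROLE_PBMC, None, day, None),
        SampleInfo(patient_id, f"{patient_id}_CORE", ROLE_CORE, None, day, None),
        SampleInfo(patient_id, f"{patient_id}_MARGIN", ROLE_MARGIN, None, day, None),
        SampleInfo(patient_id, f"{patient_id}_PLASMA_A", ROLE_PLASMA, "A", day, None),
    ]
    pbmc, core, margin, plasma_a = [s.sample_name for s in samples]

    used: set[tuple[str, int]] = set()
    variants: list[SimVariant] = []

    def next_cosmic_id() -> str:
        cosmic_counter[0] += 1
        return f"COSV{cosmic_counter[0]:07d}"

    def add(sim_class: str, ccf_core: float, ccf_margin: float) -> None:
        gene = panel[int(rng.integers(0, len(panel)))]
        key = _draw_key(rng, gene, intervals, used)
        is_cosmic = bool(rng.random() < config.cosmic_fraction)
        vaf_core = 0.5 * config.tumour_purity * ccf_core
        vaf_margin = 0.5 * config.tumour_purity * ccf_margin
        vaf_plasma = 0.5 * config.shed_fraction * (ccf_core + ccf_margin) / 2.0
        variants.append(
            SimVariant(
                key=key,
                gene=gene,
                cosmic_id=next_cosmic_id() if is_cosmic else "",
                in_hnscc_cosmic_subset=is_cosmic,
                sim_class=sim_class,
                true_vaf={pbmc: 0.0, core: vaf_core, margin: vaf_margin,
                          plasma_a: vaf_plasma},
            )
        )

    for _ in range(config.n_truncal_variants):
        add(CLASS_TRUNCAL, 1.0, 1.0)
    for _ in range(config.n_core_private):
        add(CLASS_CORE_PRIVATE, float(rng.uniform(config.ccf_min, config.ccf_max)), 0.0)
    for _ in range(config.n_margin_private):
        add(CLASS_MARGIN_PRIVATE, 0.0, float(rng.uniform(config.ccf_min, config.ccf_max)))

    for _ in range(config.n_germline_per_patient):
        gene = panel[int(rng.integers(0, len(panel)))]
        key = _draw_key(rng, gene, intervals, used)
        af = 0.5 if rng.random() < 0.8 else 1.0
        variants.append(
            SimVariant(
                key=key, gene=gene, cosmic_id="", in_hnscc_cosmic_subset=False,
                sim_class=CLASS_GERMLINE,
                true_vaf={pbmc: af, core: af, margin: af, plasma_a: af},
            )
        )
    for _ in range(config.n_chip_per_patient):
        gene = panel[int(rng.integers(0, len(panel)))]
        key = _draw_key(rng, gene, intervals, used)
        af = float(rng.uniform(*config.chip_vaf_range))
        variants.append(
            SimVariant(
                key=key, gene=gene, cosmic_id="", in_hnscc_cosmic_subset=False,
                sim_class=CLASS_CHIP,
                true_vaf={pbmc: af, core: 0.0, margin: 0.0, plasma_a: af},
            )
        )

    depth_of = {
        pbmc: config.mean_depth_pbmc,
        core: config.mean_depth_tumour,
        margin: config.mean_depth_tumour,
        plasma_a: config.mean_depth_plasma,
    }
    for sv in variants:
        for name in (pbmc, core, margin, plasma_a):
            sv.calls[name] = _sample_call(rng, depth_of[name], sv.true_vaf[name])

    sim = PatientSim(patient_id=patient_id, samples=samples, variants=variants)
    if config.recurrence is not None:
        simulate_serial_plasma(config, rng, sim, cosmic_counter)
    return sim


def simulate_serial_plasma(
    config: SimConfig,
    rng: np.random.Generator,
    sim: PatientSim,
    cosmic_counter: list[int],
) -> None:
    """Extend a patient with post-treatment plasma timepoints B-D (in place).

    Non-resistant somatic clones disappear from plasma after treatment; the
    truncal (resistant) clone follows the scenario's regrowth multipliers;
    acquired variants (tumour-absent, HNSCC-COSMIC flagged) appear from the
    onset timepoint.  Germline and CHIP backgrounds persist unchanged.
    """
    scen = config.recurrence
    if scen is None:
        raise ValueError("config.recurrence must be set")
    somatic = [sv for sv in sim.variants if sv.sim_class in SOMATIC_CLASSES]
    if not somatic:
        raise ValueError(f"patient {sim.patient_id}: recurrence scenario needs somatic variants")

    pbmc = f"{sim.patient_id}_PBMC"
    plasma_a = f"{sim.patient_id}_PLASMA_A"
    tps = ("B", "C", "D")
    names = {tp: f"{sim.patient_id}_PLASMA_{tp}" for tp in tps}
    for tp, day in zip(tps, scen.plasma_days):
        sim.samples.append(
            SampleInfo(sim.patient_id, names[tp], ROLE_PLASMA, tp, day,
                       scen.recurrence_day)
        )

    # acquired variants, absent from tumour and baseline plasma
    panel = config.panel()
    iv = panels.gene_intervals()
    intervals = {
        r.gene: (r.chrom, int(r.start), int(r.end)) for r in iv.itertuples(index=False)
    }
    used = {(sv.key.chrom, sv.key.pos) for sv in sim.variants}
    baseline_names = [s.sample_name for s in sim.samples if s.sample_name not in names.values()]
    acquired: list[SimVariant] = []
    for _ in range(scen.n_acquired_variants):
        gene = panel[int(rng.integers(0, len(panel)))]
        key = _draw_key(rng, gene, intervals, used)
        cosmic_counter[0] += 1
        sv = SimVariant(
            key=key, gene=gene, cosmic_id=f"COSV{cosmic_counter[0]:07d}",
            in_hnscc_cosmic_subset=True, sim_class=CLASS_ACQUIRED,
            true_vaf={n: 0.0 for n in baseline_names},
        )
        sv.true_vaf["__acquired_level__"] = float(rng.uniform(*scen.acquired_vaf_range))
        acquired.append(sv)

    onset_index = tps.index(scen.acquired_onset_timepoint) if scen.acquired_onset_timepoint in tps else 0
    for sv in acquired:
        level = sv.true_vaf.pop("__acquired_level__")
        for i, tp in enumerate(tps):
            sv.true_vaf[names[tp]] = level if i >= onset_index else 0.0
        for name in baseline_names:
            sv.calls[name] = _sample_call(
                rng,
                config.mean_depth_plasma if name == plasma_a else (
                    config.mean_depth_pbmc if name == pbmc else config.mean_depth_tumour
                ),
                0.0,
            )
    sim.variants.extend(acquired)

    for sv in sim.variants:
        if sv.sim_class == CLASS_ACQUIRED:
            pass  # per-timepoint fractions already set
        elif sv.sim_class == CLASS_GERMLINE:
            for tp in tps:
                sv.true_vaf[names[tp]] = sv.true_vaf[pbmc]
        elif sv.sim_class == CLASS_CHIP:
            for tp in tps:
                sv.true_vaf[names[tp]] = sv.true_vaf[plasma_a]
        elif sv.sim_class == CLASS_TRUNCAL and scen.resistant_clone:
            base = sv.true_vaf[plasma_a]
            for tp, mult in zip(tps, scen.regrowth_multipliers):
                sv.true_vaf[names[tp]] = min(base * mult, 1.0)
        else:  # non-resistant somatic clones cleared by treatment
            for tp in tps:
                sv.true_vaf[names[tp]] = 0.0
        for tp in tps:
            sv.calls[names[tp]] = _sample_call(
                rng, config.mean_depth_plasma, sv.true_vaf[names[tp]]
            )


def simulate_cohort_mem(config: SimConfig) -> CohortSim:
    """Simulate a cohort fully in memory (the file-free entry point)."""
    rng = np.random.default_rng(config.seed)
    cosmic_counter = [0]
    patients = [
        simulate_patient(config, rng, f"P{i + 1:03d}", cosmic_counter)
        for i in range(config.n_patients)
    ]
    return CohortSim(config=config, patients=patients)


# ---------------------------------------------------------------------------
# file output

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
]


def _chrom_sort_key(chrom: str):
    body = chrom.removeprefix("chr")
    return (0, int(body)) if body.isdigit() else (1, body)


def write_patient_vcf(sim: PatientSim, path: str | os.PathLike) -> None:
    """Write one patient's samples as a plain-text multi-sample VCF 4.2."""
    names = sim.sample_names()
    chroms = sorted({sv.key.chrom for sv in sim.variants}, key=_chrom_sort_key)
    lines = list(_VCF_HEADER_LINES)
    lines.extend(f"##contig=<ID={c},length=250000000>" for c in chroms)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names))
    for sv in sorted(sim.variants, key=lambda s: (_chrom_sort_key(s.key.chrom), s.key.pos)):
        fields = [
            sv.key.chrom, str(sv.key.pos), sv.cosmic_id or ".", sv.key.ref, sv.key.alt,
            ".", "PASS", ".", "GT:DP:AD",
        ]
        for name in names:
            c = sv.calls[name]
            if c.depth == 0:
                gt = "./."
            elif c.alt_reads == 0:
                gt = "0/0"
            elif c.alt_reads / c.depth > 0.9:
                gt = "1/1"
            else:
                gt = "0/1"
            fields.append(f"{gt}:{c.depth}:{c.depth - c.alt_reads},{c.alt_reads}")
        lines.append("\t".join(fields))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_annotation_table(cohort: CohortSim, path: str | os.PathLike) -> None:
    seen: dict[VariantKey, tuple[str, str]] = {}
    for p in cohort.patients:
        for sv in p.variants:
            if sv.key not in seen:
                seen[sv.key] = (sv.gene, sv.cosmic_id)
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "gene": gene, "cosmic_id": cid}
        for k, (gene, cid) in sorted(seen.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_cohort(
    config: SimConfig, outdir: str | os.PathLike, force: bool = False
) -> CohortSim:
    """Simulate and write a pipeline-ready cohort directory.

    Outputs: ``vcfs/<patient>.vcf``, ``samples.tsv``, ``annotation.tsv``,
    ``cosmic_hnscc.txt``, ``truth.tsv``.  Identical config (including seed)
    gives byte-identical files.
    """
    outdir = os.fspath(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    os.makedirs(os.path.join(outdir, "vcfs"), exist_ok=True)

    cohort = simulate_cohort_mem(config)
    for p in cohort.patients:
        write_patient_vcf(p, os.path.join(outdir, "vcfs", f"{p.patient_id}.vcf"))
    write_sample_sheet(cohort.sample_sheet(), os.path.join(outdir, "samples.tsv"))
    write_annotation_table(cohort, os.path.join(outdir, "annotation.tsv"))
    with open(os.path.join(outdir, "cosmic_hnscc.txt"), "w", newline="\n") as fh:
        for cid in sorted(cohort.cosmic_subset()):
            fh.write(cid + "\n")
    cohort.truth_frame().to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False,
        float_format="%.6g", lineterminator="\n",
    )
    return cohort
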