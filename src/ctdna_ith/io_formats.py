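"""Domain types and file formats for the multi-region tumour / plasma pipeline.

The unit of analysis is one patient: a matched PBMC (germline control),
a tumour core and advancing-margin biopsy, and one to four serial plasma
samples (timepoint A at resection, B/C/D post-treatment).  All per-patient
variant evidence lives in a :class:`PatientVariantTable`, built from a
multi-sample VCF plus a sample sheet that maps VCF sample names to roles.

Conventions
-----------
* Coordinates are 1-based (VCF convention); multi-allelic records are split
  into one row per alternate allele and no further normalisation is applied.
* VAF is always recomputed as ``alt_reads / depth``; frequency fields in the
  VCF are ignored so that caller dialects cannot drift the analysis.
* A depth-0 call means "absent, untestable": its VAF is NaN and every
  downstream presence test fails.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import pysam

# Sample roles
ROLE_PBMC = "PBMC"
ROLE_CORE = "CORE"
ROLE_MARGIN = "MARGIN"
ROLE_PLASMA = "PLASMA"
ROLES = (ROLE_PBMC, ROLE_CORE, ROLE_MARGIN, ROLE_PLASMA)

PLASMA_TIMEPOINTS = ("A", "B", "C", "D")


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single-allele genomic variant (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("multi-allelic alt must be split upstream")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """Read evidence for one variant in one sample."""

    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("depth and alt_reads must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(f"alt_reads {self.alt_reads} > depth {self.depth}")

    @property
    def vaf(self) -> float:
        """alt_reads / depth; NaN when depth is 0 (untestable site)."""
        if self.depth == 0:
            return math.nan
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class Annotation:
    """Gene symbol and COSMIC status of a variant.

    ``in_hnscc_cosmic_subset`` is true iff the COSMIC ID is listed in the
    supplied upper-aerodigestive-tract subset file; it drives the rescue rule
    of the somatic filter and the "COSMIC annotated" denominators downstream.
    """

    gene: str = ""
    cosmic_id: str = ""
    in_hnscc_cosmic_subset: bool = False

    def __post_init__(self) -> None:
        if self.in_hnscc_cosmic_subset and not self.cosmic_id:
            raise ValueError("in_hnscc_cosmic_subset requires a cosmic_id")


EMPTY_ANNOTATION = Annotation()


@dataclass(frozen=True)
class SampleInfo:
    patient_id: str
    sample_name: str
    role: str
    timepoint: str | None  # A-D for plasma, None otherwise
    collection_day: int  # days relative to treatment completion
    recurrence_day: int | None  # clinical recurrence, per patient


class SampleSheet:
    """Role/timepoint/collection-day metadata for every sequenced sample.

    The sheet is the single source of sample semantics; VCF sample names
    carry none.  Invariants enforced: one PBMC per patient, at most one core,
    one margin and one plasma sample per timepoint, and plasma timepoint
    order A<B<C<D must agree with collection-day order.
    """

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples: list[SampleInfo] = list(samples)
        self._by_name: dict[str, SampleInfo] = {}
        for s in self.samples:
            if s.role not in ROLES:
                raise ValueError(f"unknown role {s.role!r} for sample {s.sample_name}")
            if s.role == ROLE_PLASMA and s.timepoint not in PLASMA_TIMEPOINTS:
                raise ValueError(
                    f"plasma sample {s.sample_name} needs a timepoint in {PLASMA_TIMEPOINTS}"
                )
            if s.sample_name in self._by_name:
                raise ValueError(f"duplicate sample name {s.sample_name}")
            self._by_name[s.sample_name] = s
        self._validate()

    def _validate(self) -> None:
        for pid in self.patients():
            rows = self.for_patient(pid)
            n_pbmc = sum(1 for s in rows if s.role == ROLE_PBMC)
            if n_pbmc != 1:
                raise ValueError(f"patient {pid} has {n_pbmc} PBMC samples, expected 1")
            for role in (ROLE_CORE, ROLE_MARGIN):
                if sum(1 for s in rows if s.role == role) > 1:
                    raise ValueError(f"patient {pid} has more than one {role} sample")
            plasma = sorted(
                (s for s in rows if s.role == ROLE_PLASMA), key=lambda s: s.timepoint
            )
            tps = [s.timepoint for s in plasma]
            if len(tps) != len(set(tps)):
                raise ValueError(f"patient {pid} has duplicate plasma timepoints")
            days = [s.collection_day for s in plasma]
            if days != sorted(days):
                raise ValueError(
                    f"patient {pid}: plasma timepoint order disagrees with collection days"
                )

    # -- lookups -----------------------------------------------------------
    def __contains__(self, sample_name: str) -> bool:
        return sample_name in self._by_name

    def info(self, sample_name: str) -> SampleInfo:
        try:
            return self._by_name[sample_name]
        except KeyError:
            raise KeyError(f"sample {sample_name!r} not in sample sheet") from None

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def for_patient(self, patient_id: str) -> list[SampleInfo]:
        return [s for s in self.samples if s.patient_id == patient_id]

    def _unique_role(self, patient_id: str, role: str) -> str | None:
        for s in self.for_patient(patient_id):
            if s.role == role:
                return s.sample_name
        return None

    def pbmc_sample(self, patient_id: str) -> str:
        name = self._unique_role(patient_id, ROLE_PBMC)
        assert name is not None  # guaranteed by _validate
        return name

    def core_sample(self, patient_id: str) -> str | None:
        return self._unique_role(patient_id, ROLE_CORE)

    def margin_sample(self, patient_id: str) -> str | None:
        return self._unique_role(patient_id, ROLE_MARGIN)

    def plasma_samples(self, patient_id: str) -> dict[str, SampleInfo]:
        """Plasma samples keyed by timepoint letter, in A-D order."""
        out = {
            s.timepoint: s
            for s in self.for_patient(patient_id)
            if s.role == ROLE_PLASMA
        }
        return {tp: out[tp] for tp in PLASMA_TIMEPOINTS if tp in out}

    def recurrence_day(self, patient_id: str) -> int | None:
        for s in self.for_patient(patient_id):
            if s.recurrence_day is not None:
                return s.recurrence_day
        return None


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read the sample-sheet TSV.

    Columns: patient_id, sample_name, role, timepoint, collection_day,
    recurrence_day (empty cells allowed in the last three).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "patient_id",
        "sample_name",
        "role",
        "timepoint",
        "collection_day",
        "recurrence_day",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            SampleInfo(
                patient_id=row.patient_id,
                sample_name=row.sample_name,
                role=row.role,
                timepoint=row.timepoint or None,
                collection_day=int(row.collection_day),
                recurrence_day=int(row.recurrence_day) if row.recurrence_day else None,
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "sample_name": s.sample_name,
            "role": s.role,
            "timepoint": s.timepoint or "",
            "collection_day": s.collection_day,
            "recurrence_day": "" if s.recurrence_day is None else s.recurrence_day,
        }
        for s in sheet.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PatientVariantTable:
    """Variants x samples evidence matrix for one patient."""

    patient_id: str
    variants: list[VariantKey]
    samples: list[str]
    calls: dict[tuple[VariantKey, str], VariantCall]
    annotations: dict[VariantKey, Annotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValueError(f"duplicate variant keys in patient {self.patient_id}")
        for v in self.variants:
            for s in self.samples:
                if (v, s) not in self.calls:
                    raise ValueError(f"missing call for {v} in sample {s}")

    def call(self, variant: VariantKey, sample: str) -> VariantCall:
        return self.calls[(variant, sample)]

    def annotation(self, variant: VariantKey) -> Annotation:
        return self.annotations.get(variant, EMPTY_ANNOTATION)

    def annotate(self, annotations: Mapping[VariantKey, Annotation]) -> None:
        """Attach annotations; unlisted variants keep the empty annotation."""
        for v in self.variants:
            if v in annotations:
                self.annotations[v] = annotations[v]

    def sorted_variants(self) -> list[VariantKey]:
        return sorted(self.variants)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (variant, sample)."""
        rows = []
        for v in self.sorted_variants():
            ann = self.annotation(v)
            for s in self.samples:
                c = self.call(v, s)
                rows.append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "gene": ann.gene,
                        "cosmic_id": ann.cosmic_id,
                        "sample": s,
                        "depth": c.depth,
                        "alt_reads": c.alt_reads,
                        "vaf": c.vaf,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "pos",
                "ref",
                "alt",
                "gene",
                "cosmic_id",
                "sample",
                "depth",
                "alt_reads",
                "vaf",
            ],
        )


class VcfFormatError(ValueError):
    pass


def _format_int(value) -> int:
    if value is None:
        return 0
    if isinstance(value, (tuple, list)):
        value = value[0]
    try:
        return int(value)
    except (TypeError, ValueError):
        return 0


def read_multisample_vcf(
    path: str | os.PathLike,
    sample_sheet: SampleSheet,
    *,
    depth_tag: str = "DP",
    allele_depth_tag: str = "AD",
) -> PatientVariantTable:
    """Read one patient's multi-sample VCF into a :class:`PatientVariantTable`.

    Every VCF sample name must resolve through the sample sheet, and all
    samples must belong to the same patient.  Multi-allelic records are split
    into one row per alternate allele; the alt-read count is taken from the
    allele-depth FORMAT field (``AD``-style: ref count first, then one count
    per alt).  Missing genotype entries become depth-0 calls.
    """
    with pysam.VariantFile(os.fspath(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise VcfFormatError(f"{path}: VCF has no samples")
        patient_ids = set()
        for name in sample_names:
            if name not in sample_sheet:
                raise VcfFormatError(f"{path}: sample {name!r} not in sample sheet")
            patient_ids.add(sample_sheet.info(name).patient_id)
        if len(patient_ids) != 1:
            raise VcfFormatError(
                f"{path}: samples span multiple patients {sorted(patient_ids)}"
            )
        patient_id = patient_ids.pop()

        variants: list[VariantKey] = []
        seen: set[VariantKey] = set()
        calls: dict[tuple[VariantKey, str], VariantCall] = {}
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                try:
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                except ValueError as exc:
                    raise VcfFormatError(
                        f"{path}: malformed record at line for {rec.chrom}:{rec.pos}: {exc}"
                    ) from exc
                if key in seen:
                    raise VcfFormatError(f"{path}: duplicate variant {key}")
                seen.add(key)
                variants.append(key)
                for name in sample_names:
                    fmt = rec.samples[name]
                    depth = _format_int(fmt.get(depth_tag))
                    ad = fmt.get(allele_depth_tag)
                    if ad is None:
                        alt_reads = 0
                    elif isinstance(ad, (tuple, list)):
                        idx = alt_index + 1  # AD = (ref, alt1, alt2, ...)
                        alt_reads = _format_int(ad[idx]) if idx < len(ad) else 0
                    else:
                        alt_reads = _format_int(ad)
                    if depth == 0:
                        alt_reads = 0
                    alt_reads = min(alt_reads, depth)
                    calls[(key, name)] = VariantCall(depth=depth, alt_reads=alt_reads)
    return PatientVariantTable(
        patient_id=patient_id,
        variants=variants,
        samples=sample_names,
        calls=calls,
    )


def read_cosmic_list(path: str | os.PathLike) -> set[str]:
    """Read the COSMIC upper-aerodigestive-tract ID list (one ID per line)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_annotation_table(
    path: str | os.PathLike, cosmic_subset: set[str] | frozenset[str] = frozenset()
) -> dict[VariantKey, Annotation]:
    """Read the variant annotation TSV (chrom, pos, ref, alt, gene, cosmic_id).

    Keys are normalised exactly as in VCF reading (1-based, single alt).
    A duplicate key with a conflicting gene symbol is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "cosmic_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[VariantKey, Annotation] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        ann = Annotation(
            gene=row.gene,
            cosmic_id=row.cosmic_id,
            in_hnscc_cosmic_subset=bool(row.cosmic_id) and row.cosmic_id in cosmic_subset,
        )
        if key in out and out[key].gene != ann.gene:
            raise ValueError(
                f"conflicting gene for {key}: {out[key].gene!r} vs {ann.gene!r}"
            )
        out[key] = ann
    return out


def write_variant_table(table: PatientVariantTable, path: str | os.PathLike) -> None:
    """Write the per-(variant, sample) evidence table as TSV (round-trippable)."""
    df = table.to_frame().drop(columns=["vaf"])
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(
    path: str | os.PathLike, patient_id: str, sample_sheet: SampleSheet | None = None
) -> PatientVariantTable:
    """Re-read a TSV written by :func:`write_variant_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "cosmic_id": str},
                     keep_default_na=False)
    samples: list[str] = list(dict.fromkeys(df["sample"]))
    variants: list[VariantKey] = []
    calls: dict[tuple[VariantKey, str], VariantCall] = {}
    annotations: dict[VariantKey, Annotation] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        if key not in annotations:
            variants.append(key)
            if row.gene or row.cosmic_id:
                annotations[key] = Annotation(gene=row.gene, cosmic_id=row.cosmic_id)
            else:
                annotations[key] = EMPTY_ANNOTATION
        calls[(key, row.sample)] = VariantCall(int(row.depth), int(row.alt_reads))
    return PatientVariantTable(
        patient_id=patient_id,
        variants=variants,
        samples=samples,
        calls=calls,
        annotations={k: v for k, v in annotations.items() if v is not EMPTY_ANNOTATION},
    )


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | os.PathLike) -> list[str]:
    """Write each named result table as ``<outdir>/<name>.tsv``.

    Row order is made deterministic by sorting on (chrom, pos, ref, alt) when
    those columns exist, otherwise on all columns; reruns on identical input
    produce byte-identical files.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise PermissionError(f"output directory not writable: {outdir}")
    written = []
    for name, df in tables.items():
        df = df.copy()
        key_cols = [c for c in ("patient_id", "chrom", "pos", "ref", "alt") if c in df.columns]
        if key_cols:
            df = df.sort_values(key_cols, kind="mergesort")
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        written.append(path)
    return written
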