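# Methods

## Scope and data model

The package analyses one patient at a time from four kinds of samples: a
PBMC germline control, tumour core and advancing-margin biopsies, and one to
four plasma cell-free DNA draws (timepoint A at resection; B, C, D
post-treatment). The pipeline starts from called, annotated variants — a
multi-sample VCF per patient with per-sample depth (`DP`) and allele-depth
(`AD`) FORMAT fields — never from reads. VAF is always recomputed as
alt_reads / depth; any frequency field in the VCF is ignored so that caller
dialects cannot change results. Coordinates are 1-based; multi-allelic
records are split into one row per alternate allele and no further
normalisation is applied (input is assumed normalised). A depth-0 call is
treated as "absent, untestable": its VAF is NaN, so every threshold
comparison fails and the variant cannot be present in that sample.

## Somatic selection cascade

Variants are selected per patient by four rules applied in a fixed order
(`somatic_filter`):

1. **R1, germline removal** — PBMC depth ≥ 20 and PBMC VAF > 10 %.
2. **R2, minimum evidence** — otherwise removed if no tumour/plasma sample
   has ≥ 4 alt-supporting reads. PBMC reads never count as support;
   rescuing a variant on germline reads would defeat the subtraction.
3. **R3, untestable germline** — otherwise removed if PBMC depth < 20 and no
   tumour/plasma sample has VAF > 20 % with ≥ 10 reads.
4. **R4, COSMIC rescue** — any removed variant whose COSMIC ID is in the
   supplied upper-aerodigestive-tract subset is restored *to candidacy*.

Percentage cut-offs are strict (>), count/coverage cut-offs inclusive (≥).
After the cascade a universal presence floor applies per sample: a kept
variant is *present* in a sample iff depth ≥ 1, alt reads ≥ 1 and
VAF ≥ 0.1 % (inclusive). R4 restores candidacy only, so the 0.1 % floor
binds rescued variants too. The floor is not applied to the PBMC sample
(its presence is never consumed downstream); the stated threshold concerns
tumour and plasma samples.

Two wordings of the evidence rule are defensible: requiring ≥ 4 supporting
reads of the *kept* set (implemented default) or *restoring*
germline-removed variants that have ≥ 4 supporting reads elsewhere. The
default is the only reading that yields a somatic rather than
germline-dominated set; the alternative is available via
`FilterThresholds(restore_removed_with_support=True)`.

CHIP (clonal haematopoiesis) variants are handled implicitly: they appear
in PBMC and plasma, so when their PBMC VAF exceeds 10 % at adequate depth
they fall to R1; low-VAF CHIP below that cut-off can survive the filter,
which is a known limitation of pure germline subtraction.

## Spatial heterogeneity

A variant present in core or margin is classified CORE_ONLY, MARGIN_ONLY or
SHARED; plasma-only variants are NOT_IN_TUMOUR and excluded from every
spatial denominator. The heterogeneity rate is the site-exclusive fraction
(1 − shared proportion) over tumour-present variants. Summaries default to
the COSMIC HNSCC subset (the clinically interpretable variants) and can be
widened to all variants. Cohort values are unweighted means over patients
with at least one tumour-present variant, reported with the min–max range;
a variant-pooled cohort rate is also emitted as a secondary figure.
Gene-level summaries average, over the patients carrying tumour-present
variants of the gene, each patient's per-gene exclusive proportion; the
packaged 19-gene panel (TCGA HNSCC top mutated genes) is the default.
Group comparisons use a two-sided Student (pooled-variance) unpaired
t-test; Welch is available via a flag. A "high frequency" variant — a
crude clonality proxy in the absence of subclonal deconvolution — has
VAF strictly above 5 % in at least one tumour sub-site.

## Plasma concordance

The tumour set is the union of core- and margin-present variants; the
plasma set is the baseline (A) present set. Reported per patient:
detection rate over all tumour variants, detection rate over
high-frequency tumour variants, the exclusive fraction among detected
variants, and the plasma-only fraction. Because the plasma assay is a
9-gene targeted panel (TP53, NOTCH1, PIK3CA, KMT2D, CDKN2A, CASP8, NSD1,
FAT1, FBXW7), both sets are restricted by default to COSMIC-subset variants
in panel genes; a flag disables either restriction. Zero-denominator rates
are NaN, never 0, and are excluded from cohort means. Leave-one-out cohort
means are provided for outlier inspection.

## Temporal tracking

Variants present in the primary tumour are BASELINE; variants absent from
both tumour sub-sites but present in ≥ 1 post-treatment plasma sample
(collection day > 0) are ACQUIRED. Plasma-A-only variants receive neither
label and are reported separately — two-site sampling cannot distinguish
missed spatial heterogeneity from true acquisition, and the labels are
defined only within the study design. By default acquisition ignores
plasma-A membership; a strict mode additionally requires absence at A.
Trajectories flag persistence (consecutive positive timepoints), loss, and
re-emergence (present–absent–present). Molecular recurrence is the earliest
post-treatment collection day with ≥ 1 qualifying variant present
(default: COSMIC-subset variants, either label); plasma A never triggers
it. Lead time = clinical recurrence day − detection day; with no
qualifying detection it is undefined, not 0.

## Synthetic cohorts

The simulator (`synthetic_data`) emits pipeline-ready VCFs, sample sheet,
annotation table, COSMIC subset list and a ground-truth table. Its model:

* **Clonal geometry** — a truncal clone (CCF 1) in both sub-sites plus
  core-private and margin-private variants with CCF ~ Uniform(0.3, 0.9).
  Expected sub-site VAF = 0.5 × purity × CCF. Defaults (4 truncal + 13 + 13
  private per patient) give a configured site-exclusive fraction of
  26/30 ≈ 0.87, the high-heterogeneity regime of a two-site head-and-neck
  cohort; 9 patients by default.
* **Plasma shedding** — baseline plasma VAF = 0.5 × shed_fraction × mean
  sub-site CCF, a linear scalar chosen because the analysis only needs
  ordering and monotonicity, not a biophysical shedding model.
* **Read sampling** — depth ~ Poisson(mean), alt reads ~ Binomial(depth,
  VAF); means 59× (tumour, PBMC) and 84× (plasma) match the sequencing
  design. This is the minimal model under which the VAF thresholds have
  calibratable sampling error.
* **Backgrounds** — 30 germline variants per patient (VAF 0.5 or 1.0 in
  every sample) and 3 CHIP variants (VAF ~ Uniform(0.01, 0.1) in PBMC and
  plasma only) exercise the subtraction path.
* **Recurrence scenario** — optional serial plasma B–D: non-resistant
  clones drop to zero, the truncal (resistant) clone follows per-timepoint
  regrowth multipliers (dormancy-then-re-emergence expressible as
  (0, 0, x)), and acquired variants appear from an onset timepoint at
  VAF ~ Uniform(0.01, 0.1). Default timepoint days (56, 118, 365) and
  recurrence day 102 reproduce the patient-1 46-day lead-time geometry.
  Acquired variants carry an HNSCC-subset COSMIC ID: they model the
  oncogenic panel variants worth tracking, and COSMIC membership is what
  lets a tumour-absent variant with few plasma reads survive the evidence
  rule — without it acquisition recovery is structurally impossible under
  the default cascade.

Purity 0.6 and shed_fraction 0.05 are conventional placeholders, not
study-derived estimates. Positions are drawn uniquely from nominal per-gene
intervals; no sequence context, sequencing error, UMIs or copy number are
simulated, so passing recovery tests demonstrates correctness of the
*analysis logic* under binomial sampling noise, not robustness to artefact
modes of real libraries. All randomness flows from one seeded
`numpy.random.Generator`; identical configs give byte-identical outputs.

## Verification sizes and numerical choices

The test suite and the acceptance script verify: exact agreement of the
cascade with an independently written rule evaluator on 10,000 randomized
boundary-spanning records; ≥ 99 % germline removal and ≥ 95 % truncal
retention on a 50-patient cohort; recovery of a configured exclusive
fraction of 0.7 within ±0.03 at 500× depth (50 patients, per-patient
standard error ≈ 0.012); monotonicity of the mean detection rate over the
shed-fraction grid {0, 0.01, 0.05, 0.2, 1} with exact zero at zero
shedding (50 patients per point); exact acquired-label recovery for every
sampled acquired variant on 20 recurrence patients; the 46-day patient-1
lead time; and byte-level determinism of simulate + pipeline. These cohort
sizes keep every check well-powered while the whole suite runs in seconds.
Ties and degenerate inputs: zero-variant patients yield NaN-flagged
summaries; result tables are sorted on (patient, chrom, pos, ref, alt)
before writing so reruns are byte-identical.

## Known limitations

Single-alt normalisation is assumed upstream; indels are accepted by the
format contract but untested territory. No subclonal deconvolution, CCF
estimation, tumour-fraction estimation or survival analysis is attempted.
The acquired/baseline dichotomy inherits the study design's ambiguity about
unsampled spatial heterogeneity. Low-VAF CHIP can leak through germline
subtraction, as noted above.
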