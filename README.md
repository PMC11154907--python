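# ctdna-ith

Analysis pipeline for quantifying spatial and temporal intra-tumoural
heterogeneity (ITH) from multi-region tumour sequencing and serial plasma
circulating tumour DNA (ctDNA) in head and neck squamous cell carcinoma
(HNSCC)-style cohorts — plus a clonal cohort simulator that makes every
stage verifiable against known ground truth.

It is written for translational genomics groups comparing tumour-informed
and tumour-naïve liquid-biopsy read-outs: given per-patient multi-sample
variant calls (PBMC germline control, tumour core, tumour advancing margin,
and plasma timepoints A–D), the pipeline

1. **selects somatic variants** per patient by germline/CHIP subtraction
   with rescue rules: remove variants with PBMC VAF > 10 % at ≥ 20×
   coverage; require ≥ 4 supporting reads in a tumour/plasma sample;
   rescue poorly covered germline sites when a sample shows VAF > 20 %
   with ≥ 10 reads; restore known HNSCC COSMIC variants; then apply a
   0.1 % VAF presence floor per sample (VAF = alt reads / depth);
2. **quantifies spatial ITH** as the proportion of tumour variants
   exclusive to a single sub-site, ITH = 1 − |shared| / |tumour-present|,
   at variant, gene, patient and cohort level, with an unpaired t-test for
   group comparisons;
3. **measures ctDNA concordance** of baseline plasma against the tumour:
   detection rate |plasma ∩ tumour| / |tumour|, the same over
   high-frequency variants (tumour VAF > 5 %, a crude clonality proxy),
   sub-site exclusivity among detected variants, and the plasma-only
   fraction — restricted by default to a 9-gene plasma panel;
4. **tracks temporal heterogeneity**: labels variants *baseline* (present
   in the primary tumour) vs *acquired* (post-treatment plasma only),
   builds per-timepoint VAF trajectories (persistence, loss,
   re-emergence), and computes the molecular lead time — days between the
   first positive post-treatment plasma sample and clinical recurrence.

## Worked example

Simulate a 9-patient cohort at study-like conditions (59× tumour, 84×
plasma, ~87 % configured site exclusivity, recurrence scenario with serial
plasma) and run every stage:

```python
import ctdna_ith as ci

cfg = ci.SimConfig(n_patients=9, recurrence=ci.RecurrenceScenario(), seed=7)
cohort = ci.simulate_cohort_mem(cfg)
results = ci.run_cohort(cohort.tables(), cohort.sample_sheet())

het = results.cohort_heterogeneity
print(f"cohort heterogeneity rate: {100*het['mean_heterogeneity_rate']:.1f}% "
      f"(range {100*het['rate_min']:.1f}-{100*het['rate_max']:.1f}%)")
row = results.concordance[results.concordance.patient_id == "cohort"].iloc[0]
print(f"ctDNA detection, all tumour variants: {100*row['detection_rate_all']:.1f}%")
print(f"ctDNA detection, high-frequency variants: {100*row['detection_rate_highfreq']:.1f}%")
print(results.recurrence_calls.head(3).to_string(index=False))
```

prints

```
cohort heterogeneity rate: 85.7% (range 76.5-94.1%)
ctDNA detection, all tumour variants: 49.3%
ctDNA detection, high-frequency variants: 48.9%
patient_id  detection_day  clinical_recurrence_day  lead_time_days
      P001             56                      102              46
      P002             56                      102              46
      P003             56                      102              46
```

The heterogeneity rate is the unweighted per-patient mean fraction of
COSMIC-annotated tumour variants seen in only one sub-site — close to the
simulator's configured 26/30 ≈ 0.87 exclusive fraction. The detection
rates are cohort means over the 9-gene plasma panel at the default
shedding fraction of 0.05; raising shedding raises them monotonically.
Each recurrence call says the first variant-positive post-treatment plasma
draw (day 56) preceded clinical recurrence (day 102) by 46 days.

The same run from the shell:

```bash
ctdna-ith simulate --outdir cohort --seed 7 --n-patients 9 --recurrence
ctdna-ith all --vcf-dir cohort/vcfs --sample-sheet cohort/samples.tsv \
    --annotation cohort/annotation.tsv --cosmic-list cohort/cosmic_hnscc.txt \
    --outdir cohort/results
```

writes TSVs for the filter audit trail, spatial classes, per-patient and
per-gene summaries, concordance, trajectories and recurrence calls. Real
cohorts are analysed the same way from per-patient multi-sample VCFs (with
`DP`/`AD` FORMAT fields), a sample sheet, an annotation table and a COSMIC
ID list; thresholds are configurable via `--config` (YAML).

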