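# glycohex

A tested, reusable implementation of the quantitative analysis chain used in
systems-glycobiology studies of colorectal cancer (CRC): N-glycan
classification and glycome summarization, TMT glycopeptide quantitation,
cell-of-origin correlation analysis, hexosaminidase (Hex) activity assay
processing, and plasma-activity-based survival stratification.

## Who this is for

Glycoproteomics and clinical-biomarker groups who have the standard exports
of such a study — glycomics EIC abundance tables, glycopeptide-spectrum-match
(glycoPSM) tables with TMT reporter intensities, protein→cell-origin
annotation maps, fluorometric plate readings, and survival cohort tables —
and want the downstream numerics to be reproducible and testable. Every
input format has a synthetic generator with known ground truth, so the whole
chain can be exercised (and its recovery properties measured) without any
external data.

## The analysis chain

1. **Glycan classification** — generic monosaccharide compositions
   (Hex/HexNAc/dHex/NeuAc) are partitioned by an ordered, serializable rule
   table into paucimannose (Man1–3GlcNAc2Fuc0–1, "M1"–"M3F"),
   chitobiose core, oligomannose, hybrid, complex, and other; classes map
   onto biosynthetic pathways (truncation / elongation / precursor).
2. **Glycome summarization** — per-sample class shares (% of total EIC),
   within-class species shares, pathway usage, paired tumor/normal ratios,
   and group comparisons (t test or ANOVA + Tukey).
3. **TMT quantitation** — glycoPSMs are filtered at PEP2D < 0.001, grouped
   by (accession, site, composition) with reporter intensities summed,
   normalized to the pooled 126 reference channel of each plex, then
   within-channel median-normalized, and merged across batches. The fully
   normalized matrix is invariant to per-channel and per-plex
   multiplicative perturbations.
4. **Cell-origin correlation** — marker scores (summed normalized abundance
   of annotation-set members) are correlated with glycan-class shares by
   Pearson's r with t-distribution significance.
5. **Hex assay** — 4-methylumbelliferone (4-MU) standard curves, MUG/MUGS
   activities, the HEXB proxy (MUG − MUGS, clamped at 0), plate
   normalization to control samples, and MTT viability percentages.
6. **Survival** — Kaplan–Meier curves, log-rank tests, 75th-percentile
   dichotomization of plasma activity, and univariable/multivariable Cox
   proportional-hazards fits (Efron ties) with Wald CIs.

## Worked example

```python
from glycohex import synthetic as syn, glycome_quant as gq, stats_survival as ss

# 36-sample tissue cohort at the default group profiles, no sampling noise
design = syn.CohortDesign()
glycome = syn.generate_glycome_table(design, syn.default_profiles(design, "tissue", 0.0), seed=1)
print(gq.type_summary(glycome)[["control_01", "II_01"]].round(2))

# 380-donor plasma cohort with proportional-hazards survival structure
cohort = syn.generate_survival_cohort(syn.SurvivalSimConfig(), seed=1)
crc = cohort[cohort.group != "healthy"].copy()
crc["event"] = crc["event"].astype(int)
print(ss.cox_fit(crc, ["activity", "age"]).summary.round(3))

labels, thr = ss.dichotomize_percentile(crc["activity"].to_numpy())
hi, lo = crc[labels == "high"], crc[labels == "low"]
chi2, p = ss.logrank(hi["time"], hi["event"], lo["time"], lo["event"])
print(f"75th-percentile threshold {thr:.3f}: {len(hi)} high / {len(lo)} low, log-rank p = {p:.4f}")
```

prints

```
                 control_01  II_01
glycan_class
paucimannose           6.70  14.10
chitobiose_core        2.80   2.58
oligomannose          24.26  22.33
hybrid                 8.40   7.73
complex               57.85  53.26
other                  0.00   0.00
            coef     hr  hr_ci_low  hr_ci_high     se      p
covariate
activity   1.361  3.899      1.773       8.575  0.402  0.001
age        0.013  1.013      0.995       1.032  0.009  0.162
75th-percentile threshold 1.208: 76 high / 226 low, log-rank p = 0.0078
```

The class-share table shows the paucimannose elevation planted in the stage
II profile (14.1% vs 6.7% in normal adjacent tissue) recovered exactly at
zero dispersion. The Cox fit on one simulated cohort recovers a strong
activity effect (the planted population hazard ratio is 2.04 per activity
unit; single-cohort estimates scatter around it), and dichotomizing plasma
activity at its 75th percentile separates survival curves (log-rank
p = 0.0078 here).

## Command line

A thin CLI wraps the library: `glycohex simulate | quantify | glycotype |
correlate | hexassay | survival | report` (see `glycohex --help`). `report`
runs the whole chain end to end on synthetic inputs and writes per-stage
provenance to `run_report.json`.

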