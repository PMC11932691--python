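# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Glycan classification

Compositions carry four residue counts: Hex (mannose + galactose), HexNAc,
dHex (core fucose) and NeuAc. Classification is an ordered rule table over
these counts, evaluated first-match-wins:

1. HexNAc ≤ 2, Hex = 0 → chitobiose core
2. HexNAc = 2, 1 ≤ Hex ≤ 3, NeuAc = 0 → paucimannose
3. HexNAc = 2, Hex ≥ 4, dHex = 0, NeuAc = 0 → oligomannose
4. HexNAc = 3, Hex ≥ 5 → hybrid
5. HexNAc ≥ 3 → complex
6. otherwise → other

Composition-level conventions where structure would be needed to decide:

* **Hex4HexNAc2** is called oligomannose. Paucimannose is defined as the
  truncated Man1–3 species only, so Man4 falls on the canonical side.
* **Fucosylated Hex≥4/HexNAc2** (e.g. Hex5HexNAc2dHex1) cannot be canonical
  oligomannose and is classed *other* — composition alone cannot resolve
  what it is.
* **Hybrid vs complex** from HexNAc count is a heuristic
  (HexNAc = 3 & Hex ≥ 5 → hybrid). Real assignments require MS/MS structure
  elucidation, which is out of scope; the rule table is serializable as TSV
  so an alternative convention can be loaded without code changes.
* NeuGc, sulfation and phosphorylation are not modeled.

Pathway mapping is total and fixed: paucimannose and chitobiose core →
truncation; hybrid and complex → elongation; oligomannose and other →
precursor. Classifying *other* as precursor is the conservative choice for
pathway-usage summaries (such species are neither demonstrably truncated
nor elongated); it only affects compositions outside the four rule classes.

## Synthetic cohorts

The generators define the study conditions under which the pipeline is
validated; all are pure functions of (config, seed).

**Discovery cohort.** 7 donors per CRC stage I–IV plus 8 controls
(36 samples) over four TMT-10plex batches. Samples are dealt round-robin
with staggered per-group offsets, giving 9 samples per plex with every
stage and a control present in every batch; channel 126 carries the pooled
reference.

**Glycome profiles.** Group-mean paucimannose shares: tissue — NAT 6.7%,
stages I–IV 13.5/14.1/14.8/15.4% (the stage range end-points with interior
stages interpolated); PBMC — control 14.9%, stages 19.5/22.0/24.6/27.1%.
The non-paucimannose remainder is split in fixed proportions
(chitobiose 3%, oligomannose 26%, hybrid 9%, complex 62% of the remainder),
a plausible tissue glycome dominated by complex-type glycans. Within-class
weights put M2F + M3F at 65% of the paucimannosidic class (the middle of
the observed 60–70% band), spread the rest over M1–M3, and populate the
canonical classes with representative species (Man5–Man9, two hybrid and
three complex compositions).

**Sample-level noise** is logistic-normal: class log-shares are perturbed
with i.i.d. Gaussian noise (SD = `dispersion`) and softmax-renormalized.
This was chosen over a Dirichlet because the dispersion parameter acts
directly on the log scale and dispersion 0 degenerates exactly to the group
means, which makes round-trip tests exact. Within-class species weights are
held fixed; only class-level composition varies.

**GlycoPSM tables.** Each feature's per-sample fold change (the truth map)
is converted to channel intensities; the reference channel carries the
pooled mean across all 36 samples, emulating a pooled reference aliquot.
Features spawn 1–5 PSMs with Dirichlet-split intensities (sums preserved),
and per-plex batch factors, per-channel biases and lognormal noise are
multiplicative — so the two-stage normalization must remove them exactly at
zero noise. A configurable decoy fraction receives PEP2D ≥ 0.001.

**Plate assays.** Standards follow fluorescence = slope·conc + intercept +
N(0, σ); sample wells encode true activities through the same line with the
planted product equal to activity × time × input amount; blanks read the
intercept. Technical triplicates for MUG and MUGS.

**Plasma cohort.** 302 CRC donors and 78 healthy controls. (Age, activity)
are bivariate normal with means/SDs 63.9/12.7 years and 1.0/0.3 relative
activity units and correlation 0.2 — the age–activity confounding strength
is not an observable we can match, so a mild positive value was fixed once;
it is configurable. Event times are exponential with hazard
h₀·exp(β_act·activity + β_age·age) and administrative censoring at 5
years. The default coefficients are ln 2.04 and ln 1.03 (the multivariable
values). The baseline hazard is calibrated deterministically (1-D Gaussian
quadrature + root bracketing) so the expected event fraction equals 87/302;
an exponential baseline (rather than Weibull) is sufficient for
hazard-ratio recovery and keeps the calibration a single integral. Healthy
controls draw activity from N(0.81, 0.25) — set so the survivor-vs-healthy
separation is in the observed AUC range — and carry no survival columns.
Survivor/nonsurvivor labels are assigned from the simulated outcome.

What the generators do **not** emulate: raw spectra and chromatography,
isotope impurity, interference between co-isolated precursors, missing-data
mechanisms other than feature-absent-from-plex, non-proportional hazards,
and real biological covariance between glycome classes. Passing tests
therefore demonstrate correctness of the numerics under the stated models,
not robustness to every artifact of real data.

## TMT quantitation

PSMs are retained at PEP2D strictly below the threshold (default 0.001) and
grouped by (accession, site, composition, plex) with channel-wise sums, so
per-channel totals are conserved exactly. Reference normalization divides
by the same-plex reference channel; a zero/missing reference excludes the
feature from that plex with a log record instead of raising. The
within-channel statistic is the **median of ratios** (configurable to
mean/total): the exact statistic used by common processing suites is not
standardized, and the median is robust to the minority of truly changed
features. Missing values are propagated, never imputed; downstream
statistics use pairwise-complete observations. Upstream search-engine FDR
control is consumed as given; only the PEP2D threshold is applied here.
For within-sample isoenzyme comparisons (HEXA vs HEXB in one channel)
reference normalization can be skipped (`quantify(..., reference=False)`).

Note that after within-channel normalization each column is anchored to its
own median, so recovered values are fold changes relative to the column's
typical feature; between-sample ratios of any feature reproduce the planted
truth exactly at zero noise (asserted to 1e-9 relative error).

## Cell-origin correlation

The marker score is the **sum** of normalized abundances over the set's
detected members (mean and log-space variants are provided); the summed
score weights abundant markers more, which matches how bulk signals
combine. Correlations are Pearson with two-sided t-distribution p
(t = r√(n−2)/√(1−r²), n−2 df), pairwise-complete; cells with n < 3 or a
zero-variance margin are flagged not-computable rather than raising.

## Hex assay

Activities are 4-MU amount per minute per input amount before plate
normalization; all cross-sample comparisons use plate-normalized relative
activity units (each plate divided by the mean of its control samples —
mean by default, median configurable). Negative blank-corrected signals are
clamped to 0 with a warning, as is a negative HEXB proxy (MUGS > MUG
signals assay failure, not biology). The standard curve requires ≥ 3
distinct concentrations and warns below R² = 0.98. Viability is
100·(treated − blank)/(vehicle − blank). Wet-lab robustness factors
(storage, freeze/thaw, tube type) are experimental QC, not computation;
only group comparisons over a factor column are supported.

## Statistics

* Two-sided tests throughout, α = 0.05.
* Pearson p from the t distribution as above; verified against exhaustive
  permutation on small fixtures.
* AUC is the Mann–Whitney statistic with half-credit for ties, verified
  against the O(n²) pairwise oracle.
* Outlier flagging replaces the proprietary ROUT procedure with a
  documented robust rule: |x − median| > k·MAD (scaled MAD, k = 5 default).
  MAD = 0 flags nothing. Flags are reported, never silently removed.
* Kaplan–Meier, log-rank and Cox fits delegate to lifelines; Cox uses the
  Efron tie correction (ties are measure-zero under the continuous-time
  generator but Efron is the better general default). Wald 95% CIs.
* Percentile dichotomization uses the linear-interpolation quantile
  convention; values strictly above the threshold are "high". On 302
  distinct values a strict 75th percentile yields a 76/226 split; published
  cohort splits that differ (e.g. 81/221) are data-dependent (ties or a
  different convention) and are not reproducible from the convention alone.

## Recovery experiments

`glycohex.validation` plants known population quantities and measures what
the pipeline recovers. Replicate seeds spawn from one base seed via
`numpy.random.SeedSequence`. Problem sizes follow the cohort design:
correlation recovery uses 2000 replicates at n = 36/35; Cox recovery uses
500 replicates of 302-donor cohorts (a few tens of seconds on one CPU).
Hazard ratios are summarized by the **geometric mean** across replicates
(exp of the mean coefficient): the coefficient is the asymptotically normal
quantity, and an arithmetic mean of HRs would carry a Jensen bias of about
HR·Var(β̂)/2 (~6% at this design's information content) that reflects the
averaging scale, not estimator quality. The mean Pearson estimate is
expected slightly below the planted value (E[r] ≈ ρ − ρ(1−ρ²)/(2n), about
−0.005 at n = 36), a property of the estimator itself.

## Known limitations

* Classification is composition-level; isomers, structures and masses are
  out of scope.
* The hybrid/complex heuristic misclassifies low-mannose hybrids.
* The synthetic glycome's non-paucimannose composition is a fixed
  convention, not fitted to data; only the paucimannose shares and the
  M2F+M3F band are pinned to observed values.
* Cox modeling covers time-fixed covariates only; no frailty, competing
  risks or time-varying effects.
* The pipeline consumes annotation sets as files; it performs no live
  queries of expression atlases.
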