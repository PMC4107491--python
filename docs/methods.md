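# Methods

`mirserum` implements the pre-analytical QC and analysis workflow for serum
miRNA qRT-PCR panel studies: hemolysis quantification and screening,
endogenous-control selection, ΔCt normalization, calibrated fold-change
analysis, rank-based cohort comparisons with multiplicity control, sample
clustering, and longitudinal concordance — together with a synthetic cohort
generator that reproduces the measurement structure these procedures assume.
This note records the models, the defaults and why, and what the synthetic
validation does and does not demonstrate.

## Measurement model

A panel measures ~742 miRNA assays per serum sample as threshold cycles
(Ct); lower Ct means higher abundance, and a reaction that never crosses
threshold is *undetected*. Undetected reactions are treated as absence
throughout — they are censored to missing, never imputed or clipped to a
numeric ceiling.

**Hemoglobin.** Free hemoglobin is estimated spectrophotometrically by the
Harboe method,

    Hb [g/l] = (167.2·A415 − 83.6·A380 − 83.6·A450) / 1000,

a three-point background correction around the 415 nm Soret peak. The
formula is linear and reads a flat spectrum as zero. Samples at or above
0.1 g/l are classified hemolysed; the boundary itself counts as hemolysed
(on real matched data the empirical gap — clean ≤ 0.075, lysed ≥ 0.154 —
makes the convention immaterial, but it must be fixed). Small negative
estimates (≥ −0.005 g/l) are background noise and clamp to zero with a
warning; anything more negative indicates mis-ordered absorbances and is an
error.

**QC filters.** Two detection thresholds are deliberately distinct:
reactions above Ct 35 are excluded outright (along with assays showing >1
melting peak and reactions within 5 cycles of an amplifying negative
control), while presence/absence calls for detection-fraction rules use
Ct < 34. Boundaries are read literally: Ct 35.0 survives the reaction
filter, Ct 34.0 is not a presence call, and a detection fraction of exactly
80% passes. Whether the "within 5 Ct of the negative control (Ct > 35)"
rule is one rule or two is ambiguous in common usage; both are applied
independently here, which is the conservative reading.

**Inter-plate calibration.** Identical calibrator reactions on every plate
estimate per-plate offsets; each plate is shifted by (its mean calibrator
Ct − grand mean of plate means). Within-plate differences are preserved
exactly and the operation is idempotent.

## Normalization and endogenous-control selection

ΔCt = reference Ct − assay Ct, so higher ΔCt means higher relative
abundance, and fold change between matched conditions is
FC = 2^(ΔCt_case − ΔCt_control). The reference is a single assay, the
arithmetic mean Ct of an assay pair (equivalently the geometric mean of the
linear quantities), or the per-sample global mean over assays detected in
every sample.

Two selection procedures are implemented, matching how serum panels are
actually normalized:

* **Within-pair ratio stability** (matched designs): restricted to assays
  detected in all paired samples, the linear ratio per pair is
  2^(Ct_first − Ct_second). Candidates are assays whose ratio stays below 2
  in every pair, ordered by the SD of their ratios. This is the right
  criterion when only intra-individual comparisons are made; a liver-type
  assay can win here while being strongly person-variable.
* **Cross-cohort SD ranking**: restricted to assays detected in every
  pooled sample, rank ascending by the SD of the linear quantity 2^(−Ct),
  with a global-mean pseudo-assay included for comparison. Because the
  criterion operates on linear quantities, it is abundance-dominated: the
  winners sit at the low-abundance end of the ubiquitously detected set,
  and the printed SDs of real rankings (~1e−10) correspond to Ct ≈ 31–33.
  Ties rank lexicographically for deterministic output.

The global mean is included as a comparator rather than a recommendation:
in hemolysed samples the abundant assays that dominate a global mean are
largely blood-cell-derived, which biases the reference itself.

## Fold-change cutoff calibration

The significance cutoff for fold-change calls is not fixed a priori.
A technical replicate pair (one serum, two independent extractions and
quantifications) measures the assay's own false-call behaviour: the
fraction of co-detected assays whose replicate fold difference reaches
2-, 3- and 4-fold. The chosen cutoff is the smallest threshold whose
fraction stays within a configured budget (default 10%). Under the
calibrated noise model the median fractions are ≈30%/9%/4%, so the budget
selects 3-fold — the conventional choice for serum panels. Because a
single pair's fractions carry ±2–3 percentage points of binomial noise,
the pipeline also reports a consensus cutoff from the median fractions
across replicate pairs; single-pair calibrations near the budget boundary
should not be over-read.

## Screens and tests

**Hemolysis screen.** Red cells carry abundant miRNAs, so hemolysis
inflates blood-cell-derived assays. On matched lysed/unlysed pairs,
normalized within pair to a single pair-stable reference, an assay is
flagged when (a) it is ≥3-fold up-regulated in at least 50% of pairs, or
(b) it is detected below Ct 34 in at least half the lysed samples and in no
matched unlysed sample. The 50% rule denominates *all* pairs by default
(an assay measurable in only one or two pairs cannot be flagged by a single
noisy excursion); counts against the evaluable-pair denominator are also
reported, and the denominator is configurable. Down-regulation is reported
but never flags. The screen normalizer deliberately differs from the
cross-cohort reference pair to avoid circularity.

**Hemoglobin / covariate correlation screens.** Per assay, Pearson R
against the covariate with the t transform on n−2 df, pairwise-complete.
The hemoglobin screen applies Benjamini–Hochberg control (many true
responders are expected); the triglyceride screen defaults to uncorrected
two-sided p-values, which is how per-covariate correlation tables for small
panels are conventionally reported, with BH available by flag.

**Group comparisons.** Two-sided Mann–Whitney per assay on ΔCt, exact for
combined n ≤ 16 without ties (the 7–10 per group regime sits here) and the
tie-corrected normal approximation otherwise, with BH across all tested
assays. Assays entirely missing in a group are skipped and listed.

**Clustering.** Average-linkage (UPGMA) hierarchical clustering of samples
on 1 − Pearson r distances over pairwise-complete assays. Leaf order is
deterministic: children of each merge are visited by (merge height,
lexicographically smallest leaf). The dendrogram exports to Newick.

**Longitudinal concordance.** For matched within-person sample pairs,
Pearson R per pair over assays detected in ≥19 of 24 samples (the fraction
scales to other cohort sizes), plus a differential-detection list: assays
detected (below Ct 34) in at least half of the first samples and never in
the matched seconds, or vice versa, cross-referenced against the hemolysis
flag list.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is validated.

**Panel.** 742 assays in tiers: 2 reference assays (biologically stable,
jump-immune, at the low-abundance end of the ubiquitous set, Ct ≈ 32.6/33);
2 within-pair stable assays (technically tight and hemolysis-insensitive
but strongly person-variable — good within-pair normalizers, poor
cross-cohort controls); 1 exogenous spike-in (Ct ~ N(23.3, 0.6²),
independent of everything); 162 blood-cell-derived assays — 126 expressed
in clean serum (12 abundant, the rest at Ct 28.5–32.4) with hemolysis
slopes of 3–4 cycles per doubling of hemoglobin, and 36 absent from clean
serum (nominal Ct 41) with slopes of 6–7.5 so they surface below Ct 34 in
hemolysed samples; 16 serum background assays; 16 sporadically expressed
assays (per-subject expression probability 0.3–0.85); and a never-expressed
remainder. The design is deterministic for a given design seed.

**Hemolysis effect.** In hemolysed samples (Hb ≥ 0.1 g/l) blood-cell
assays shift down in Ct by slope · log2(Hb / 0.05); below the hemolysis
threshold the red-cell contribution is negligible against the serum
background and no shift is applied. True Ct floors at 8 cycles
(amplification saturates).

**Noise.** Replicate error has two Ct-dependent components. A tight base
error (SD 0.17 cycles, rising to a cap of 0.175 above Ct 28) drawn from a
variance-matched bounded uniform — melting-curve QC removes gross outliers
from exports, so surviving base deviations are bounded. And near-discrete
threshold-cycle jumps: above Ct 28 a reaction's Ct slips, with probability
ramping to 0.32, by 1.0–1.55 cycles in either direction, reflecting
Poisson sampling of the few template molecules present at high Ct. The
jumps, not the base error, carry the large replicate fold deviations;
coincident opposite-sign jumps in the two replicates produce the rare
≥4-fold excursions. No single unimodal error law reproduces the measured
fraction profile of a serum panel — the near-3:1 drop from 2-fold to
3-fold exceedances together with a thin ≥4-fold tail — at the observed
detection count; the two-component law does. Reactions above Ct 35 are
censored to missing.

**Calibration.** The noise and abundance-tier parameters were fitted by
simulation (grid plus random search) against four joint targets measured on
1000 technical-replicate pairs: median co-detected assays ≈ 157; median
fractions of co-detected assays ≥2/3/4-fold apart ≈ 31%/9%/3%; ≥95% of
≥2-fold assays at raw Ct > 28; and a median 3-fold fraction below the 10%
budget so the cutoff calibration selects 3. Measured at the frozen
defaults: 157, 30.2%, 8.9%, 3.8%, with 98% of ≥2-fold assays above Ct 28.

**Other scenario parameters.** Clean hemoglobin is uniform on
0.035–0.075 g/l and lysed hemoglobin log-uniform on 0.15–2.45 g/l,
matching the ranges of real matched-pair measurements. Triglyceride is
uniform on 50–210 mg/dl non-fasting with fasting values at 35–85% of the
matched non-fasting draw. Longitudinal pairs drift by a per-subject,
per-assay Gaussian with SD drawn from 0.2–0.75 cycles, scaled by each
assay's biological lability (so the designated controls drift least), and
independent of elapsed time — within-person profile correlations show no
time trend. Plates (one per sample) carry N(0, 0.15²) offsets removed by
inter-plate calibration; calibrator wells have 0.02-cycle noise.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the *procedures* behave as specified under
a measurement model with realistic structure: censoring-aware detection
rules, abundance-dependent replicate noise, log-linear hemolysis response,
binary per-subject expression, plate offsets. They do not reproduce any
real study's assay identities: which human miRNAs are hemolysis-sensitive,
triglyceride-correlated, or suitable controls is a property of real serum
that no simulation can certify, and published panel studies of this design
deposit no raw data to compare against. Known simplifications: expression
is binary per subject (real marginal assays drift in and out of detection
within a person, so the generator's detection Venn across a matched cohort
only loosely matches published counts); the hemolysis response is exactly
log-linear above threshold; fluorescence curves, melting profiles and
diet-derived exogenous miRNAs are not modelled. The default longitudinal
cohort produces per-pair correlations of ~0.91–0.95 — above the 0.87 floor
reported for real within-person pairs, but without the 0.99 extremes, since
the generator's abundance spread among ubiquitous assays is narrower than a
real serum panel's.

## Numerical conventions

Missing values are dropped pairwise, never imputed. All rankings break
ties lexicographically by assay id; dendrogram leaf order is deterministic.
Exact Mann–Whitney p-values are used only in the tie-free small-n regime.
The Harboe clamp window is −0.005 g/l. Fold changes are always computed
from ΔCt differences, so per-sample additive shifts (plate offsets,
loading differences) cancel identically. Seeded runs are bit-reproducible:
one generator seed drives every stochastic draw in a fixed order.
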