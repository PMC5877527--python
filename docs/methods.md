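# Methods

## Synthetic cohort model

The generator emulates a small case–control COPD study: `n_copd = 25`
patients (all male; GOLD A/B/C/D = 2/2/4/17) and `n_control = 21` healthy
never-smoker controls (9 M / 12 F). It produces three blocks from one master
seed (split into independent child streams, so identical configurations are
byte-reproducible):

**Clinical table.** Continuous variables are sampled by inverse-CDF from
truncated normals moment-matched to the configured median/IQR targets
(SD = IQR/1.349), truncated at the configured limits. Pack-years are log-normal
(right-skewed); exacerbation counts are negative-binomial (size 2, mean
median + 0.2) clipped to 0–2; mMRC is a rounded truncated normal. FEV1 (L)
is derived as FVC × FEV1/FVC so the spirometric identity holds exactly, and
the COPD arm's FEV1/FVC is truncated below 0.7, the disease-defining
criterion. GOLD categories are assigned by descending FEV1 %predicted
(A = best preserved) and carry their definitional semantics: A/B capped at
one exacerbation/year, A/C at mMRC ≤ 1, B/D forced to mMRC ≥ 2. Medication
prevalence scales with stratum severity (patients are treated according to
their GOLD group), comorbidity flags are severity-independent Bernoullis.

**Targeted panel.** ~70 Biocrates-p180-style analytes (amino acids,
biogenic amines, acylcarnitines, lysoPC/PC/SM/SM(OH) species, hexose) are
log-normal around class-typical serum concentrations (µM) with a common
log-SD `analyte_log_sd = 0.35`. Planted contrasts are standardized shifts
on the log scale, default sizes 0.8–1.5 (directions follow the COPD
metabolomics literature; magnitudes are conventional design choices):
SM and SM(OH) down in COPD, PUFA-PCs
(C36–C40, ≥ 2 double bonds) down, lysoPCs up; stratum markers lysoPC↑ in A,
kynurenine↑ in B, putrescine↑/ornithine↓ in C. COPD-vs-control shifts are
multiplied by a per-stratum severity (`gold_severity` = 0.5/0.8/0.9/1.0 for
A–D) so mild patients sit metabolically between controls and severe
disease. Derived ratios (Glu/Gln, Kynurenine/Trp, Putrescine/Ornithine,
Ornithine/Ser, Thr/Ser, tSM totals and their quotient) are recomputed after
all shifts, so ratio consistency is exact by construction.

**Untargeted spectra.** Per (matrix ∈ {serum, EBC}, mode ∈ {pos, neg}) the
cohort shares ~400 peak locations uniform on 90–1400 Da with heavy-tailed
baseline intensities (log-normal, log-SD 1.5). Each subject's spectrum adds
(i) independent peak noise (`noise_sd = 0.4` log units; EBC scaled by
`ebc_noise_scale = 0.4` because the dilute EBC matrix carries less
biological variance), (ii) a rank-one latent composition factor with
loadings of SD `spectral_factor_sd = 0.5` log units — the block-correlation
option that mimics plasma protein/lipoprotein composition variance and
makes the serum profile the dominant, group-uninformative source of total
variance, as expected for PC1 — and (iii) a multiplicative batch factor
exp(N(0, `batch_scale_sd` = 0.5²)) that TIC normalization must cancel.
Planted group signals sit at fixed bins (serum-neg 327/367/368 lower in
COPD; serum-neg 1069/1317 higher in GOLD B; serum-pos 259 higher in GOLD A),
sized in units of `noise_sd`. m/z positions jitter by 0.03 Da per subject.

**Planted subtypes.** With `subtype_effect > 0` the COPD arm splits into
two latent subtypes; the second receives alternating-sign standardized
shifts across the targeted panel, shifts at a deterministic subset of serum
peak locations, and a mean shift of the serum latent factor (a subtype that
differs in overall serum composition). This is the ground-truth structure
the phenotyping workflow is asked to recover; it is off by default.

What the generator does *not* emulate: chromatography, isotope patterns,
adducts, missing values, analyte-level covariance beyond the single latent
factor, age/sex effects on metabolites, or instrument drift. Passing tests
therefore demonstrate correctness and calibration of the *analysis*, not
robustness to those real-data complications.

## Preprocessing decisions

- Binning: nearest integer, round-half-up; bins retained even when empty so
  feature sets align across subjects. Out-of-range peaks raise by default
  (`strict`), or are dropped with a warning (`lenient`).
- TIC normalization divides by the summed intensity; an all-zero spectrum
  is an explicit error.
- Log transform: natural log with pseudocount 1e-6 on TIC fractions.
- The logistic transform 1/(1 + 2e⁻ˣ) is applied to **centered** log
  fractions (per-bin mean removed across subjects). Raw log TIC fractions
  sit near −6, deep in the logistic's saturated tail, which would collapse
  all spectral variance; centering places each bin's between-subject
  variation in the transform's responsive range. `center_spectral=False`
  restores the uncentered composition.
- Clinical/targeted columns are divided by their maximum; 0/1 indicators
  are left as is; an all-zero numeric column is left unscaled with a
  warning rather than failing the whole integration.

## Statistical conventions

Student's t with pooled variance (Welch behind `equal_var=False`); raw
p-values without multiple-testing correction (a Benjamini–Hochberg column is
available via `add_bh_fdr` but off by default); ANOVA + Tukey HSD via the
studentized range, with strata of n < 2 dropped (strict mode errors) and an
optional omnibus gate (`tukey_gate`) that runs the post hoc test only where
ANOVA is significant. Association cells are flagged notable at |r| ≥ 0.49 or
p < 0.05. Exacerbation counts enter the association table as a 0/1/2 factor
via ANOVA. The volcano "fold change" is the difference of group means on the
integrated [0, 1] scale, since ratios are unstable near zero.

## Multivariate decisions

PCA is centered but not variance-scaled (all features already live in
[0, 1]); the sign convention makes each loading's largest-magnitude entry
positive. Sparse PLS-DA retains **exactly** `keepX` entries per component by
magnitude-ranked soft thresholding (ties resolve to the earliest index);
selection-count semantics, not a penalty path, are the contract. Classes
are dummy-coded and centered; cross-validated tuning predicts by nearest
training-class centroid in score space and minimizes the balanced error
rate, with ties broken toward fewer components, then smaller `keepX`.
Classes smaller than the fold count fall back to leave-one-out within the
class; CV training folds may then contain singleton classes, which the
internal fit tolerates.

## Validity indices

All indices are computed from their definitions on the Euclidean distance
matrix. Variant pinning where the literature has several: Dunn uses
single-linkage between-cluster separation over maximum cluster diameter;
the C-index uses the l smallest/largest pairwise distances with l = number
of within-cluster pairs; membership entropy uses natural log of cluster
size proportions; silhouette assigns 0 to singletons; APN deletes one
feature column at a time and reclusters (row-deletion variants are out of
scope). Indices undefined at k = 1 or k = n are reported as NaN with a
reason; a zero maximum diameter sends Dunn to +inf. Orientation metadata
(higher-better: CH, Γ, silhouette, Dunn; lower-better: DB, C-index, APN)
drives best-k selection and control comparison; entropy and the distance
summaries are descriptive.

## Phenotyping workflow

The 24 candidate datasets are the full cross-product of cohort scope
(all subjects / COPD only) × representation (original features / principal
components explaining ≥ 5 % of the subset's variance, minimum one) × six
source subsets (all blocks; clinical; targeted; serum profiles; EBC
profiles; all metabolomic blocks). The positive control evaluates the GOLD
partition (controls as a fifth stratum when in scope) in the score space of
a sparse PLS-DA fit with those labels at fixed default hyperparameters
(2 components, keepX 60); a `space="raw"` mode evaluates
the same partition in the dataset's own feature space. Because the control
partition is label-derived, its APN is 0 by construction — a data-derived
clustering must match that stability to be accepted. "Approaching" the
control is quantified as a relative tolerance (default 10 %) per oriented
index of the Calinski–Harabasz-optimal partition; with controls in scope
the k = 2 cut must additionally misclassify ≤ 2 subjects. Inside the
workflow APN subsamples 40 deleted columns (seeded) for tractability on
~5k-feature matrices; the standalone `stability_apn` is exact.

This acceptance rule is calibrated two-sidedly: on default cohorts (group
effects only, no subtypes) no dataset is accepted — the expected negative
result — while a planted two-subtype cohort yields accepted COPD-only
candidates whose CH-optimal cut recovers the planted partition
(adjusted Rand ≈ 1).

## Problem sizes

Simulation-based checks use deliberately modest sizes chosen to make the
full suite quick on one CPU: 50 null cohorts for type-I calibration, 50
seeds for planted-feature recovery, 20 full-workflow runs for subtype
recovery, 5 for the null-acceptance check, 200 random fixtures (n ≤ 12)
for the validity-index oracles, and 20 000 permutations for the t-test
oracle. The acceptance script uses slightly smaller counts (30/25/8/4) for
the same quantities.

## Known limitations

- Generator locations for analytes and spectra are conventional, not
  calibrated to any measured cohort; only directions and relative effect
  sizes are meaningful.
- The strict "GOLD A closer to controls than to B–D" placement on the
  first supervised component is not reproducible when every COPD subject
  carries heavy smoking history and maintenance medication; the pipeline
  yields the weaker robust ordering control < A < D.
- The positive-control comparison spans two geometries (sPLS-DA score
  space vs dataset space); the relative-tolerance rule makes this explicit
  rather than hiding it, and the raw-space mode is provided for users who
  prefer a same-space comparison.
- Complete-linkage tie-breaking follows the underlying implementation's
  deterministic ordering, not a documented lowest-index rule.
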