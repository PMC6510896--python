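# Methods

`bloodspec` implements a chemometric pipeline for stratifying patients from
healthy controls (HC) by attenuated-total-reflection Fourier-transform
infrared (ATR-FTIR) spectroscopy of blood biofluids, with common variable
immunodeficiency (CVID) as the motivating disease.  This note documents the
models, the numerical choices, and what the synthetic validation data do and
do not establish.

## Data model

A spectrum is a vector of absorbances on a uniform wavenumber axis (cm⁻¹),
stored ascending (files written descending — the spectroscopic display
convention — are flipped on read).  A study is a `SpectralDataset`: a shared
axis, an `(n_spectra × n_wavenumbers)` matrix, and per-spectrum metadata
(subject, group HC/CVID, CVID subgroup with/without clinical complications,
biofluid serum/plasma, spot 1–2, replicate 1–10).  The canonical acquisition
design is 2 dried-biofluid spots × 10 point spectra = 20 replicates per
subject per biofluid; replicates of one subject are averaged
(`average_replicates`, sentinel `spot = replicate = 0`) before any
subject-level statistic, so that inference is on *n* = subjects, never
*n* = spectra.

Two analysis windows are used: the *fingerprint* region, 900–1800 cm⁻¹
(closed interval), rich in protein, nucleic-acid and carbohydrate bands, and
the *high* region, 2800–3700 cm⁻¹, dominated by C–H/O–H/N–H stretches.

## Preprocessing

Two recipes, applied per spectrum:

* **Variant A** — rubber-band baseline correction followed by vector
  normalisation.  The rubber band is the lower convex hull of the
  (wavenumber, absorbance) point set, linearly interpolated between hull
  vertices and anchored at both endpoints (single pass, no iteration, no
  wavenumber weighting); the corrected spectrum is non-negative and touches
  zero at every hull vertex.  Variant A preserves relative band intensities
  and is the input for subject-level intensity reading.
* **Variant B** — Savitzky-Golay second derivative (window 9 points,
  polynomial order 2, derivative per cm⁻¹ on the ascending axis) followed by
  vector normalisation.  The second derivative sharpens overlapping bands
  and removes baseline in one step; it is the input for classification.
  Edge points are evaluated from the polynomial fitted to the nearest full
  window (`scipy`'s `mode="interp"`), so the axis length is preserved and
  region extraction commutes with filtering.

Vector normalisation is plain unit-Euclidean-norm scaling.  Some
spectroscopy packages subtract the spectrum mean first; that dialect is
available via `center_before_norm=True` but is not the default, because the
plain scaling is idempotent and keeps non-negativity after variant A.

## PCA-LDA and cluster vectors

Spectra are mean-centred and decomposed by SVD; principal components (PCs)
are ordered by explained variance with a deterministic sign convention (the
largest-magnitude loading element is positive).  A Fisher linear
discriminant is fitted on the retained PC scores with pooled within-class
covariance, ridge-regularised by 10⁻⁸ of its trace; for more than two
classes the first generalised eigenvector of (S_b, S_w) is used.  LD1
scores are the projection of the centred scores on that direction, oriented
so the alphabetically last class has the higher mean.

**Retained PCs.** Default: the smallest count explaining ≥ 99 % of variance,
capped at min(n_subjects − 2, n_subjects / 5).  The n/5 cap is the classical
"at least five samples per discriminant dimension" rule; without it the
99 % criterion admits roughly n/2 dimensions on replicate-averaged spectra
and the discriminant direction is dominated by noise (measured on the
synthetic study, cluster-vector biomarker recovery drops from 5–6/6 to
1–3/6).  The count is configurable (`n_pcs`).

**Cross-validation** is leave-one-subject-out: all spectra of the held-out
subject are removed before both the PCA and the LDA fit of the fold, the
held-out spectra are projected through the fold's model, and each fold's
LD1 sign is aligned by its training class means.  Spectrum-level folds would
leak replicate structure.  A Welch two-tailed t-test on the held-out LD1
scores of the two classes summarises separation.

**Cluster vectors** back-project LD1 into wavenumber space: the
discriminant track is |wᵀL| per wavenumber (w = LD1 weights, L = PC
loadings); each class's pseudo-spectrum is the signed track scaled by the
class-mean LD1 score.  Track peaks are biomarker candidates.

## Classification

* **Split** — Kennard-Stone max-min Euclidean selection on subject-mean
  preprocessed spectra, run per class: the two most mutually distant
  subjects seed the training set, which grows by the subject farthest from
  it (max-min), until round(fraction × n_class) subjects are selected
  (default fraction 2/3).  The split is deterministic and patient-level: no
  subject contributes spectra to both sides.
* **Model** — RBF-kernel SVM.  (c, γ) are chosen by grid search (defaults
  c ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, powers of 4) scored by subject-grouped
  stratified k-fold cross-validation (default k = 10) pooled across folds;
  ties break toward the smallest c, then the smallest γ.  k is clamped to
  the smallest per-class subject count when a class is small (the
  three-class design has ~5 training subjects in the complication-free
  group), with a logged warning.
* **Report** — spectrum-level confusion counts on the held-out test set;
  per-class rates, sensitivity and specificity (one-versus-rest) from the
  pooled ("accumulated hits") counts, as percentages.  A true class absent
  from the test set reports NaN and is flagged, not 0.

## Biomarker extraction

Three per-wavenumber score tracks, all computed on subject-averaged
*training* spectra:

1. **t-test** — Welch two-sample test per wavenumber; score = −log₁₀ p.
2. **Cluster vector** — |wᵀL| from the PCA-LDA fit above.
3. **Forward feature selection (FFS)** — over bootstrap rounds (default
   100; 50 in the orchestrated pipeline): subjects are resampled with
   replacement within class, a PCA is refit on the resample, wavenumbers are
   ranked by the variance-weighted aggregate |loading|
   (Σₖ explained_fractionₖ·|L_kν|), and candidates are greedily retained
   while they reduce the Welch p-value of the class contrast on the running
   difference-of-means projection, subject to an alpha-to-enter gate of
   0.05 and a cap of 6 features per round.  Score = how many rounds selected
   each wavenumber.  The per-round PCA refit and the entry gate are this
   package's design: with a single fixed ranking the top-ranked wavenumber
   is trivially selected in every round, and even with both measures a
   null dataset's chance-significant wavenumbers recur in up to ~half of
   the rounds — bootstrap counts condition on the realised data, so FFS
   counts should be read as *stability within this training set*, not as a
   calibrated significance level.

From each track the **six** highest local maxima are retained greedily in
height order, discarding any candidate within **10 cm⁻¹** of an
already-retained peak (local maximum = strictly greater than both
neighbours; plateaus contribute their lowest-wavenumber point; endpoints
are eligible against their single neighbour; ties break toward the lower
wavenumber).  Per-method panels are merged with the same 10 cm⁻¹ rule;
because the three score scales are incommensurable, candidates are ordered
by within-method max-normalised score, and a peak absorbed by proximity
records its method as *corroborating* the survivor (a panel entry backed by
≥ 2 methods is flagged corroborated).  All omissions are recorded with the
rule that removed them.

**Subject-level intensity analysis** then reads each retained biomarker on
variant-A (intensity-preserving) data: per-subject means of the 20
replicates, Welch two-tailed t-tests with 95 % confidence intervals for the
contrasts HC vs CVID, HC vs CVID-without-complications, HC vs
CVID-with-complications, and between the CVID subgroups; direction
(up/down in CVID) from the sign of the CVID-minus-HC difference.  Band
labels (e.g. 1034 cm⁻¹) snap to the nearest axis point within half a step.
No multiple-testing correction is applied by default, matching common
practice of reporting raw p ≤ 0.05 in exploratory biospectroscopy;
Welch (not pooled-variance) tests are used throughout as the robust
default.

**Power analysis** (`power_min_n`): smallest group sizes, at a fixed
n_a/n_b ratio, for which a two-tailed two-sample t-test reaches a target
power under the noncentral-t model (effect size d = |Δmean| / rms sd);
minimality is verified by checking the next smaller size falls below the
target.

## Synthetic data generator

The generator emulates a dried-blood-spot ATR-FTIR study so that every
stage is testable with known ground truth:

* **Axis** 400–4000 cm⁻¹ at 4 cm⁻¹ spacing (901 points); **cohort** 30 HC,
  8 CVID complication-free, 13 CVID with complications (51 subjects,
  1020 spectra per biofluid); **replicates** 2 spots × 10 points.
* **Spectrum model** — a sum of Gaussian bands (serum-like library:
  Amide A/B/I/II/III, CH stretches, phosphate and carbohydrate fingerprint
  bands, amplitudes 0.03–0.30 a.u.).  Per subject, each band amplitude is
  base + class effect + N(0, 0.002), plus a smooth per-subject spectral
  deviation field (white noise convolved with a 16 cm⁻¹ Gaussian kernel,
  pointwise sd 0.004) modelling biological heterogeneity beyond band
  amplitudes.  Per replicate: a random quadratic baseline (coefficients
  uniform in [0, 0.01]) and white noise, sd 0.002.
* **Class effects** — additive amplitude deltas on eight reported biomarker
  bands: up in CVID at 984, 1034, 1115, 1759, 2862, 2932 cm⁻¹; down at
  1242 and 1528 cm⁻¹ (deltas 0.005–0.010 a.u.; fingerprint effects
  0.008–0.010, high-region effects weaker at 0.005–0.006, mirroring the
  weaker reported high-region classification).  Subjects in the
  complications subgroup carry delta × 1.5, giving a two-level ground truth
  for three-class experiments.  Effects sit on narrow bands (σ 10–14 cm⁻¹)
  because localising a class effect to ±8 cm⁻¹ is only physically
  meaningful when the band is comparably narrow.
* **Why the smooth field matters** — if between-subject variation were
  *only* band-amplitude noise, the per-wavenumber t-statistic of an
  affected band would be constant along the band (numerator and denominator
  both scale with the band shape), so a track's peak position would be
  unidentifiable in principle.  The smooth field gives the denominator a
  floor that is flat in wavenumber, which makes tracks peak at band
  centres.  Reported magnitudes are not calibrated to any instrument; the
  scale is chosen so variant-A normalised intensities fall near 0.1–0.15
  at major band shoulders.
* **Reproducibility** — each subject's draws come from a seed sequence
  keyed by (study seed, group, subject index), so enlarging one group never
  changes existing subjects' spectra; `generate` is bit-identical for a
  given config.
* **Null and scaled variants** — `null_variant` zeroes all deltas (classes
  exchangeable; used for type-I-error and chance-level calibration);
  `scaled_effects` multiplies all deltas (used for monotonicity checks).

**What a green synthetic test does not establish.**  The generator omits
Mie scattering, water-vapour lines, detector drift, spot-position
("coffee-ring") gradients, and any instrument-specific noise structure; its
bands are independent Gaussians, whereas real serum bands co-vary through
shared biochemistry.  Passing tests demonstrate that the *pipeline* is
correct and well calibrated on data of the stated structure — not that the
disease signal in real cohorts has this strength or localisation, and not
that the study's headline sensitivities/specificities are reproduced
(those depend on the real deposited spectra and on unreported analysis
choices such as the exact PC count and CV scheme).

## Orchestration

`run_experiment` composes simulate/load → preprocess → per-region,
per-labelling classification → per-region biomarker extraction (on the
two-class training subjects) → subject-level comparisons, and returns a
versioned, JSON-serialisable report with provenance (seed, config hash,
package version, ground truth when simulated).  Identical config + seed
gives a byte-identical `metrics.json`; `compare_reports` diffs the numeric
leaves of two reports at a tolerance and rejects mismatched schema
versions.  Configs can be loaded from YAML (`RunConfig.from_yaml`) with
unknown keys rejected.

## Known limitations

* Fisher LDA with the ridge default can still be unstable when classes are
  nearly collinear in PC space; increase the ridge or lower `n_pcs`.
* FFS selection counts are a stability measure conditioned on the training
  set (see above), not calibrated p-values.
* The Kennard-Stone fraction uses round(fraction × n) per class; reported
  real-study split sizes (e.g. 13/21 and 18/30) are not exactly 2/3 and are
  not reproduced.
* Only Gaussian band shapes are generated (no Lorentzian/Voigt option yet).
* Vendor binary formats (OPUS) and JCAMP-DX are out of scope; data enter as
  wide CSV or two-column text files with a manifest.
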