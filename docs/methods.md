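# Methods

This note records the models, algorithmic choices and numerical
conventions behind `ramanct`, and what the synthetic experiments do and
do not demonstrate.

## Data model

A `SpectralDataset` is an `(n_spectra, n_channels)` intensity matrix on a
single strictly increasing wavenumber axis (cm⁻¹), with one metadata row
per spectrum: acquisition batch, animal (`mouse_id`), disease group
(`sham`/`sick`), disease model (`PCI` polymicrobial sepsis / `LPS`
endotoxemia) and cell. Group and model vocabularies are closed; spectrum
ids are unique. Files are plain CSV in a wide (axis column + one column
per spectrum) or long/tidy dialect, each with a metadata sidecar — chosen
for portability and testability over any vendor format. Resampling onto a
common axis uses linear interpolation only (monotone, artifact-free) and
refuses to extrapolate.

## Preprocessing

Order: despike → SNIP baseline → (calibration) → clip → vector normalize.
Normalizing after clipping means the silent 1800–2800 cm⁻¹ region never
influences the scale of retained channels.

**Despiking.** Cosmic-ray events are 1–2 channel transients far above
noise. Candidates are channels whose residual from a 5-channel running
median exceeds `despike_zscore_threshold` (default 8) robust sigmas
(MAD × 1.4826) of the per-spectrum residual distribution; candidate runs
wider than `despike_max_width` (default 2) channels are left alone,
because genuine Raman bands are broad. Flagged channels are replaced by
linear interpolation across the flanking clean channels; everything else
is returned bit-identical, and repairs are capped per spectrum (default
10, keeping the largest). A 2-means variant (clustering candidate runs on
peak amplitude and width, labelling the high-amplitude cluster as spikes,
with strong outliers always included) is available via
`despike_method="kmeans"`.

*Known limitation:* with very sharp bands (FWHM ≲ 6 channels) at high
signal-to-noise, the apex residual against the running median can reach
the z = 8 threshold, trimming the apex by a few percent in a small
fraction of spectra (≈0.005 % of channels in the default simulation).
This is far inside the ≤1 % clean-channel budget and invisible after
aggregation, but users with very narrow bands should raise the threshold
or the median window.

**SNIP baseline.** The fluorescence continuum is estimated by iterative
peak clipping: at half-window p, every interior channel is replaced by
min(own value, mean of the two p-distant neighbours). The window sweeps
m…1 (`snip_decreasing=True`, the standard low-artifact variant) with
m = `snip_max_halfwidth` = 60 channels — comfortably wider than the
broadest CH-stretch band (~32 cm⁻¹ FWHM at 1 cm⁻¹ sampling) so bands are
passed under, yet much narrower than the fluorescence hump. Clipping runs
in the compressed log-log-sqrt (LLS) domain to protect the estimate from
tall peaks. Two numerical choices matter:

* the spectrum is anchored at its minimum before compression (and the
  offset restored afterwards), which makes the estimator exactly
  equivariant under constant offsets and well-defined for negative
  counts;
* a pedestal of 2× the per-spectrum dynamic range is added before the
  LLS transform and removed after. Without it the transform's strong
  curvature near zero lets the clipping erode even straight-line
  baselines (≈6 % of range); with it the residual drops below 1 % while
  the compression retains its purpose.

Clipping erodes smooth background humps by roughly A·m³/(3σ²) for a hump
of amplitude A and width σ (in channels) — negligible for realistic
fluorescence (σ ≳ 1000 cm⁻¹) but noticeable if a "background" is as
narrow as a few hundred cm⁻¹. Such structures are treated as signal by
design.

**Clipping and normalization.** Channels are kept iff their wavenumber
lies in a keep interval, inclusive on both ends (so the conventional
400–3050 cm⁻¹ working range is representable exactly); defaults are
[400, 1800] ∪ [2800, 3050] cm⁻¹. Vector normalization scales each
spectrum to unit Euclidean norm over the retained channels.

## Wavenumber calibration

Dispersive instruments drift between sessions. A 4-acetamidophenol
(paracetamol) reference is measured per day; its ASTM E1840 band
positions ship as editable data. For each literature position, the
despiked, baseline-corrected reference is searched within ±10 cm⁻¹; a
located maximum must clear the in-window median by 5 robust sigmas and is
refined by 3-point parabolic interpolation. A least-squares polynomial
(degree 2 by default — offset plus mild dispersion nonlinearity, without
overfitting a ~20-peak list) maps measured → literature positions; the
corrected axis must remain monotone, and spectra are then resampled onto
the common grid. On the synthetic reference the fit recovers a +2 cm⁻¹
shift to < 0.1 cm⁻¹ with rmse ≈ 0.08 cm⁻¹, limited by channel sampling
and noise.

## Chemometrics

**Aggregation.** Single-cell spectra are averaged in seeded random
disjoint groups of `group_size` (10 by default; 12 suits denser
imaging-mode data) drawn strictly within a (batch, mouse, group) stratum,
then re-normalized; remainders are discarded and undersized strata
dropped with a warning. Never mixing animals keeps aggregates attributable
and prevents identity leaking across cross-validation folds.

**Model.** PCA (mean-centering only — spectra are already normalized,
and per-channel scaling would distort band ratios) reduces each aggregate
to its first `n_components` scores (default 5), which feed LDA, a
500-tree random forest, or an RBF-SVM (C = 1, bandwidth from the median
pairwise-distance heuristic). For LDA the signed score is flipped, if
necessary, so the sick training mean is negative; the LD loading is the
discriminant direction back-projected through the PCA basis, with
positive excursions belonging to the sham side.

**Validation.** Stratified 10-fold CV refits PCA and classifier per fold
(plain k-fold when k exceeds the smaller class, e.g. leave-one-out).
Batchwise CV holds out one acquisition batch entirely — its spectra
contribute nothing, not even to the PCA — and so probes generalization to
a new measurement session. Batches containing a single class never rotate
into the test position; they stay in every training split and are
additionally predicted by a final all-data model. Metrics (balanced
accuracy, sensitivity = sick recall, specificity = sham recall, Cohen's κ
with κ = 0 by convention when the expected agreement is 1) are computed
from the pooled confusion matrix by their definitions; the test suite
cross-checks them against an independent implementation over an
exhaustive grid of small matrices.

**Majority vote.** Each animal takes the label of the majority of its
spectrum-level predictions; exact ties go to "sick" (in a screening
context a tied animal should be flagged), configurable via `tie_label`.
With per-spectrum balanced accuracy ~0.75 and ≥100 spectra per animal,
the binomial tail makes a wrong animal-level call vanishingly rare
(P < 10⁻⁷ per animal), so the vote concentrates to a perfect animal-level
score — the practical argument for measuring many cells per animal.

## Difference spectra and band assignment

The sick − sham difference of group mean spectra is scanned for local
extrema of both signs with prominence ≥ 3× a robust noise scale
(1.4826/√2 × the MAD of channel-to-channel increments, which ignores the
smooth band structure; after clipping no silent region remains from which
to read the noise floor directly). Peaks are annotated against a
catalogue of band assignments stored as data (`low`, `high`, `category`;
single positions have low = high): a peak matches a band if it falls in
the range widened by the tolerance (default 5 cm⁻¹, so tolerance 0 means
exact containment); overlapping categories are all reported and unmatched
peaks are labelled `unassigned`. The assignments are tentative literature
attributions, so the table is meant to be edited.

## Synthetic data generator

Spectra are built as Σ bands × effects × gains + baseline + noise +
spikes on a 350–3100 cm⁻¹, 1 cm⁻¹ grid:

* **Bands** — Gaussians at catalogue positions; fingerprint FWHM
  9–18 cm⁻¹, CH-stretch 25–32 cm⁻¹; amplitudes are generic cell-spectrum
  proportions (amide I and CH₃-stretch dominant), not biological claims.
* **Class effects** — multiplicative sick/sham ratios per band,
  exponentiated by a global `effect_scale` (0 = exact null): nucleic-acid
  bands 785/1094/1334 cm⁻¹ ×1.30/1.30/1.25 in sick; amino-acid 527/641
  and lipid-ester 1754 cm⁻¹ elevated in sham (×0.78/0.78/0.75 in sick).
  The default magnitudes are calibrated so that the default study design
  is clearly separable (k-fold balanced accuracy ≥ 0.9).
* **Hierarchy** — per-batch log-normal gain and baseline-amplitude
  factors (sd 0.03), per-mouse log-normal gain (sd 0.03) and per-band
  jitter (sd 0.01), per-cell gain (sd 0.03). The jitter default is
  deliberately small: per-animal band signatures are coherent across many
  channels, so even a few percent of jitter makes aggregates of one
  animal mutually predictable, which biases non-grouped k-fold CV
  optimistically and collapses the effective sample size to the number of
  animals. Larger values are supported (and realistic for strongly
  heterogeneous cohorts) but move the zero-effect null away from chance
  under the default study design — see "what the null shows" below.
* **Baseline** — quadratic trend plus a broad fluorescence hump
  (σ = 1800 cm⁻¹), overall ~3–8× the band amplitudes.
* **Noise and spikes** — iid Gaussian noise (sd 0.02 of band units) and
  cosmic spikes of ~30× noise at Poisson-distributed counts per spectrum
  (`spike_rate`, default 0) or an exact count (`spikes_per_spectrum`).
* **Miscalibration** — `axis_shift` displaces the recorded axis of both
  the cell spectra and the generated 4-acetamidophenol reference, so the
  calibration stage can be exercised end-to-end.

Ground truth (clean spectra, class templates, every spike, all labels)
is returned alongside the data; one seed drives all draws and identical
seeds give bit-identical datasets.

**What the generator does not emulate:** instrument response and detector
nonlinearity, fluorescence photobleaching kinetics, alginate-embedding or
substrate contributions, non-Gaussian lineshapes, channel-correlated
noise, and cohort-scale biological heterogeneity. Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour under a
controlled model, not performance on instrument data.

**What the null shows.** With `effect_scale = 0`, cross-validated
balanced accuracy should sit at chance. A single CV estimate on 160
aggregates scatters well beyond its binomial width (folds share training
models, and batchwise predictions are fold-coherent); batchwise CV is
additionally biased a few percent *below* 0.5 on null data, because the
held-out fold's spurious class-mean difference anti-correlates with the
training split's in a finite balanced dataset. The test suite and the
acceptance script therefore evaluate the null as a mean over five
independent replicates, which is the quantity that converges to 0.5.

## Problem sizes

The default synthetic study is 4 batches × 4 mice/group × 50 cells
(1600 spectra, 2751 channels → 160 aggregates), which runs the full
pipeline including both CV schemes in well under a minute on one CPU;
the null check repeats it five times. Unit tests use 2 × 2 × 10–15-cell
scaled-down versions of the same design.
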