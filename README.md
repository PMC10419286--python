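# ramanct

Chemometric analysis of single-cell Raman spectra for immune-cell
profiling: can the vibrational fingerprint of individual splenic
T-lymphocytes tell a genuinely septic animal from a sham control — and
from sterile, endotoxin-driven inflammation?

`ramanct` implements the complete desk-side analysis for this kind of
two-arm murine study:

* **Preprocessing** — cosmic-spike removal, SNIP (sensitive nonlinear
  iterative peak clipping) background subtraction in the compressed
  log-log-sqrt domain, clipping to the fingerprint (400–1800 cm⁻¹) and
  CH-stretching (2800–3050 cm⁻¹) regions, and vector (L2) normalization.
* **Wavenumber calibration** — per-day polynomial correction of the axis
  against a 4-acetamidophenol reference standard (literature band
  positions ship as an editable CSV).
* **Chemometrics** — random within-animal aggregation of single-cell
  spectra, principal component analysis feeding a linear discriminant
  (or random-forest / RBF-SVM) classifier, stratified 10-fold and
  leave-one-batch-out ("batchwise") cross-validation, balanced accuracy
  (mean per-class recall), Cohen's κ, and animal-level majority voting.
* **Difference-spectrum profiling** — group mean spectra, sick − sham
  difference spectra, prominence-based peak picking, and annotation
  against a catalogue of tentative band assignments (nucleic acids,
  proteins, lipids, amino acids).
* **Synthetic data** — a seeded hierarchical generator
  (batch → mouse → cell → spectrum) with Gaussian Raman bands,
  class-dependent band effects, fluorescence baseline, noise, cosmic
  spikes and optional axis miscalibration, returning full ground truth so
  every stage is testable without instrument data.

The model at the core is PCA-LDA on aggregated spectra: each aggregate
x ∈ ℝᵖ is reduced to its scores t = Wᵀ(x − x̄) on the first k principal
components, and LDA supplies the discriminant score s(x) = wᵀt + b with
the convention that diseased ("sick") cells score negative. The
discriminant direction back-projected into wavenumber space (the LD
loading, Ww) shows which bands drive the separation. Performance is
summarized by the balanced accuracy BA = ½(TPR + TNR) and Cohen's
κ = (p₀ − pₑ)/(1 − pₑ) from the 2×2 confusion matrix, at both the
spectrum and the animal (majority-vote) level.

Estimators follow the scikit-learn protocol (`Despiker`, `SnipBaseline`,
`RangeClipper`, `VectorNormalizer`, `WavenumberCalibrator`,
`PCAClassifier` with `fit`/`transform`/`predict` and `get_params`), so
they compose with sklearn pipelines and model selection; module-level
functions wrap them for `SpectralDataset` objects carrying the metadata
hierarchy.

## Worked example

```python
from ramanct import *

cfg = SyntheticConfig(n_batches=2, mice_per_group_per_batch=2,
                      cells_per_mouse=25, spikes_per_spectrum=1,
                      axis_shift=2.0, seed=7)
ds, truth = generate_dataset(cfg)

axis, ref = generate_reference(cfg)
_, ref_corr = snip_baseline(ref)
cal = fit_calibration(axis, ref_corr[0])

proc, spikes = preprocess_pipeline(ds, calibration=cal)
agg = aggregate_spectra(proc, AggregationSpec(group_size=10, seed=7))
res = kfold_cv(agg, k=10, n_pcs=5, classifier="lda", seed=7)
resb = batchwise_cv(agg, n_pcs=5, classifier="lda", seed=7)
d = difference_spectrum(proc, {"group": "sick"}, {"group": "sham"})
```

printing, step by step:

```
200 spectra, 2751 channels, 200 cosmic spikes injected
calibration: 20 peaks matched, rmse 0.081 cm-1
preprocessed: 1652 channels retained, 230 spike repairs
aggregated: 16 mean spectra of 10 cells each
10-fold CV: balanced accuracy 1.000, Cohen's kappa 1.000
batchwise CV: balanced accuracy 1.000
majority vote: balanced accuracy 1.000 over 8 mice
strongest difference peak: 786 cm-1 (sick side, Nucleic Acids)
```

The calibration recovered the simulated +2 cm⁻¹ axis shift to better
than 0.1 cm⁻¹; the classifier separates the two groups perfectly at this
(deliberately strong) effect size, at both spectrum and animal level; and
the dominant difference-spectrum peak lands on the 785 cm⁻¹ nucleic-acid
band that the generator elevated in the sick class — elevated DNA/RNA
signal is the expected signature of activated lymphocytes.

The same flow is available from the shell:

```sh
ramanct synth --seed 7 --out data/
ramanct preprocess --in data/spectra.csv --out data/proc.csv
ramanct model cv --in data/proc.csv --scheme batchwise --out-dir results/
ramanct diff --in data/proc.csv --group-a group=sick --group-b group=sham \
             --out-dir results/
ramanct run --config run.yaml --out-dir results/   # everything, one config
```

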