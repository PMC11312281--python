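# Methods

## The problem and the pipeline

Exogenous-sugar adulteration of honey with C3-plant syrups (rice, sugar
beet, partially inverted sugar cane) evades the classical stable-carbon-
isotope screen. Raman/SORS fingerprints respond to it directly: a honey
spectrum is dominated by fructose and glucose bands, and mixing in syrup at
a % w/w level a replaces that signature with the syrup's own — maltose
bands for rice syrup, sucrose bands for beet — as the exact convex
combination (1 − a/100)·honey + (a/100)·syrup of the underlying sugar
compositions. The pipeline estimates, from a preprocessed spectrum of an
*unseen honey type*, whether the sample is adulterated, with which syrup,
and at what level.

Stages: preprocessing → exploratory PCA → classification/regression →
leave-group-out evaluation. Each is a module with a narrow surface
(`preprocess`, `exploratory`, `models`, `evaluate`), fed either by real
spectra through `spectra_io` (wide CSV + metadata CSV) or by the
`synthetic` generator.

## Preprocessing

Fixed order: crop → ModPoly baseline → Savitzky–Golay → SNV → replicate
averaging. Averaging is deliberately last, so normalisation acts on
individual measurements.

* **Crop** to the information-rich window, closed interval: 585–1550 cm⁻¹
  (Year-2 preset) or 337.8–1470.9 cm⁻¹ (Year-1 preset).
* **ModPoly baseline** (plain min-replacement variant): iteratively
  least-squares fit a degree-*d* polynomial to the working spectrum, clip
  the working spectrum to min(working, fit), stop when the fitted curve's
  maximum relative change drops below `tol` or after `max_iter` rounds.
  The wavenumber axis is rescaled to [−1, 1] before fitting for
  conditioning. Defaults: degree 4, `max_iter` 100, `tol` 1e−3 — the
  customary defaults of the modified-polyfit family; the degree is the one
  genuinely free parameter and is exposed in `PreprocessConfig`. On
  signal-plus-background inputs the working spectrum is pointwise
  non-increasing over iterations, so the baseline converges to the lower
  envelope under the peaks. With the synthetic fluorescence model (wide
  Gaussian, σ = 600 cm⁻¹), degree 4 removes all but <1% of the background
  RMS energy over the crop window. Note that a *correlation* between
  corrected spectra and the background is not a usable removal criterion:
  the clean signal itself correlates ≈0.19 with so broad a background, so
  the residual-energy ratio is what the tests assert.
* **Savitzky–Golay**: window 31, polynomial order 7, derivative order 0;
  edges handled by the one-sided polynomial fit (`mode="interp"`), so
  polynomials of degree ≤ 7 pass through unchanged.
* **SNV**: per row, subtract the mean and divide by the standard deviation
  with the n−1 denominator (the convention of the common R implementation;
  documented because it changes nothing downstream but makes values
  reproducible). Rows whose variance is numerically zero are rejected with
  the offending measurement id.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis relies
on, not Raman physics:

* Each sugar contributes fixed Gaussian bands (centre, width, amplitude):
  maltose 865/935, sucrose 711/718/808/839, glucose 706/1047/1060/1126,
  fructose 823/872/1060 cm⁻¹, widths 8–15 cm⁻¹. Centres sit at the band
  regions known to discriminate syrup adulteration; amplitudes are free
  parameters with the defaults in `synthetic.DEFAULT_PEAKS`.
* Honey base composition: fructose 38, glucose 31, sucrose 1, maltose 2
  g/100 g, with per-type multiplicative jitter of ±10% per sugar drawn once
  per honey type (honey-to-honey variance is not quantified anywhere we
  know of; 10% is a plausible within-cluster spread for light multifloral
  honeys and is a documented free knob). Spiking syrups use measured
  HPLC-ELSD compositions: rice r01 = maltose 31.90 + glucose 22.49;
  beet b05 = sucrose 31.52 + fructose 24.74 + glucose 24.37; cane =
  fructose 21.83 + glucose 22.95 + sucrose 12.74 g/100 g.
* Per measurement: lognormal detector gain (σ = 0.10), a fluorescence
  background — one wide Gaussian, σ = 600 cm⁻¹, centre uniform on the
  axis, amplitude uniform in 0.5–3× the clean-signal maximum — and
  additive white noise (sd 0.005 intensity units, ≈1–2% of the clean
  signal maximum). These defaults are the package's standing study
  conditions: gain and fluorescence dominate, mirroring the situation the
  SNV and baseline steps exist to fix.
* Designs: `year2_design()` = 14 types × (pure ∪ {rice, beet} × {10, 20,
  30, 50}%) × 3 replicates → 126 samples / 378 spectra (70 samples per
  single-syrup subset); `year1_design()` = heather-style types with
  sugar-cane spiking at 20/40/60%.
* All randomness flows from one `SeedSequence`, so studies are
  bit-reproducible per seed.

Not modelled: real Raman cross-sections and band shapes (Lorentzian tails,
overtones), the non-uniform detector axis of a real spectrometer,
photon-migration effects of the spatial offset, matrix fluorophores beyond
one smooth background, minor sugars, and between-day batch effects.
Consequently, a clean result on synthetic data demonstrates that the
*pipeline machinery* is correct — splits leak nothing, the taxonomy
partitions errors, levels are recoverable when the band structure carries
them — not that real honeys reach any particular accuracy. On the default
conditions the five-class RF task is in fact almost error-free, which real
SORS data is not; the generator's honey-type jitter is mild compared with
real botanical variation.

## PCA

Column-mean-centred SVD on the preprocessed matrix; no column scaling (SNV
already standardises rows). Component signs are fixed by making each
component's largest-|loading| element positive. `top_loadings` ranks axis
points by the maximum absolute loading over chosen components;
`level_score_correlation` reports the Spearman correlation between spiking
level and the most level-discriminating component. 95% score ellipses use
the χ²(2) quantile of the per-group 2-D covariance.

## Models

* **PLS-DA**: PLS regression on one-hot indicators; latent dimension
  chosen by internal stratified CV accuracy over 1..max; class = argmax
  indicator score.
* **RF**: 500 trees; features-per-split tuned over {√p, p/3, p/10} by
  internal 5-fold stratified CV. The grid search runs on 100-tree forests
  and the winner is refit with the full 500 — ranking features-per-split
  candidates stabilises long before the ensemble itself, and this keeps the
  91-split experiments tractable. Impurity importances are kept, rescaled
  to max 100.
* **Ordinal RF**: Frank–Hall cumulative decomposition — K−1 binary forests
  for P(y > cₖ), monotonised by a running maximum from the top class down,
  prediction 1 + #{k : P > 0.5}. With K = 2 this is exactly the binary RF
  decision. Chosen as the transparent reading of "ordinal forest"; no
  per-forest tuning.
* **XGBoost**: 200 rounds, depth 3, learning rate 0.1, softmax objective,
  early stopping on an internal stratified 20% fold when class counts
  permit.
* **RF regression**: 500 trees on the level (% w/w, pure = 0); predictions
  clamped to [0, 100].

Ties everywhere resolve to the first class in declared order (pure < 10 <
20 < 30 < 50, rice before beet). No feature pre-selection is applied before
RF by default — selection was found counterproductive on this problem
class — but an untuned/fixed-features configuration exists for comparison
and for cheap count-only runs.

## Evaluation

`enumerate_splits` yields all C(n, k) held-out type sets in lexicographic
order. `run_experiment` trains per split on the training types' samples
only and logs one prediction per test sample; design completeness (every
type has pure + every adulterant × level) is validated up front.

Rates, with their denominators: pure→adulterated over all pure predictions
(182 for the 14-type, k = 2 design), adulterated→pure and soft over all
adulterated predictions (728), total error over all predictions (910).
Correct + hard + soft counts partition the log — asserted in the
`MetricsSummary` constructor. For the combined 9-class task "soft" is any
non-pure prediction that is not the exact (syrup, level) pair, and
rice↔beet confusion is tabulated separately. The soft denominator
(adulterated predictions, not all predictions) is a documented convention;
both numerator counts are carried in the summary so the other convention
can be recomputed.

The heather experiment runs `n_models` = 100 random stratified 75/25
resamples (stratified on the four-level label so each resample sees all
levels), fitting an untuned binary RF and an ordinal RF per resample, and
reports mean accuracy ± SD, per-class correct rates and the fraction of
perfect models. The 75/25 ratio is an assumption; the source protocol for
"variations of the training and test data" is underspecified.

## Numerical choices and degenerate inputs

* CSV round-trips are lossless: values serialised at full repr precision
  and parsed with the round-trip float parser.
* A descending input axis is reversed (with its columns) rather than
  rejected; axes must otherwise be strictly increasing and finite.
* ModPoly requires length > degree + 1; flat spectra survive baseline
  correction but are rejected at SNV (zero variance) with the measurement
  id named.
* `component_spectrum` normalises to the band model's global maximum
  (dense reference grid including the exact centres), not the on-axis
  maximum, so axes that miss every band yield near-zero signal instead of
  rescaled noise.
* Experiment seeds derive from one `SeedSequence` per run; every model fit
  receives an explicit integer seed below 2³¹.

## Problem sizes used by the test suite

Unit tests run on a scaled-down study (5 types, 2 replicates); the
end-to-end checks in `tests/test_acceptance.py` and `scripts/acceptance.py`
use the full default designs: 14 types, 91 splits for classification and
regression (rice arm in the tests; both arms in the script), 100 heather
resamples. The script prints each quantity as it is computed.

## Known limitations

* PLS-DA exposes no VIP-based importance; `variable_importance` raises for
  it by design.
* The real deposited dataset's on-disk layout is unknown here; no import
  adapter is provided beyond the generic CSV reader.
* The synthetic axis is uniform; real spectrometer axes are not, so
  feature counts after cropping differ from real-data feature counts.
* Probabilities are raw ensemble votes/softmax outputs; no calibration.
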