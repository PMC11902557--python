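# Methods

`soyspec` implements a chemometric classification workflow for visible/NIR
reflectance spectra of mechanically harvested soybean components — intact
grain, broken grain and non-grain impurities. This note records the models
and procedures, the parameters that matter, the numerical choices made where
the design was genuinely open, and what the synthetic validation data does
and does not demonstrate.

## Workflow

The pipeline order is: band trimming → SPXY partitioning → preprocessing →
feature-wavelength selection → (optional) hyperparameter tuning → classifier
training → held-out evaluation.

**Band trimming.** Line-scan VNIR spectrometers have poor signal-to-noise at
the edges of their range. Bands whose centers fall in the closed intervals
[377, 410] nm or [980, 1019] nm are removed by default. On the default
281-channel uniform grid (377–977 nm, spacing 600/280 ≈ 2.143 nm) this
leaves 265 bands. Intervals are closed — a center equal to an endpoint is
removed — as a deterministic boundary rule. The real instrument axis is
nonlinear and not published, so the grid is configurable everywhere.

**Partitioning (SPXY).** Calibration and prediction sets are split 4:1 by
Kennard–Stone-style greedy max–min selection under the joint distance
d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y. d_x is Euclidean distance
between spectra. SPXY was formulated for a continuous response; for class
labels we use the discrete metric d_y ∈ {0, 1} (same/different class),
normalized like d_x, which preserves the joint-distance structure while
being well defined for categories. Ties break toward the lowest sample
index, making the split fully deterministic. The split is computed on the
trimmed *raw* spectra so that preprocessing (whose fitted state must only
see calibration rows) cannot influence set membership.

**Preprocessing.** Eight sample-wise transforms: BC (baseline correction),
MA (moving average), SGD (Savitzky–Golay derivative), NORM (per-spectrum
min–max), SNV (standard normal variate), MSC (multiplicative scatter
correction), DS (derivative spectroscopy = plain first finite difference
per nm), SGS (Savitzky–Golay smoothing). Open choices, fixed as follows:

- *BC* is underdetermined in the chemometrics literature; the default is
  subtraction of the straight line through the spectrum's first and last
  points (endpoint-anchored linear baseline). An offset-only variant
  (subtract the per-spectrum minimum) sits behind `baseline="offset"`.
- *DS vs SGD*: DS is the raw first difference divided by band spacing
  (length n−1, grid at midpoints); SGD is the least-squares polynomial
  (Savitzky–Golay) derivative, length-preserving.
- SG defaults: window 11, polyorder 2, derivative order 1; MA default
  window 5. These are conventional values — no authoritative setting
  exists — and all are configurable. SG filtering assumes a uniform grid;
  the derivative is scaled by the mean band spacing to give nm⁻¹ units.
- MA edges use a truncated window (the mean over the part of the window
  inside the spectrum), which preserves length without padding artifacts.
- SNV uses the unbiased (n−1) standard deviation, stated explicitly to fix
  cross-implementation drift.
- MSC regresses each spectrum on a reference (x = a + b·ref, output
  (x−a)/b). Inside a calibration/prediction protocol the reference is the
  calibration-set mean, frozen at fit time; held-out rows never influence
  it. MSC is exactly idempotent under a fixed reference.

Chains compose transforms in order; DS, the only band-count-changing step,
must come last.

**Feature-wavelength selection.** Both selectors are scored by a
classification-accuracy evaluator — by default a random forest trained on
the calibration partition restricted to the candidate bands and scored on
the prediction partition. This departs from the PLS/RMSECV criterion of the
original SPA/CARS formulations deliberately: the end task is classification,
so subset size is justified by classification accuracy.

- *SPA* grows chains of minimally collinear bands: columns are mean-centered
  and each step adds the band with the largest norm after orthogonal
  projection onto the complement of the chain's span (Gram–Schmidt update;
  a dense-projector brute force serves as the test oracle). Because the
  original start-band strategy is unspecified, every band is tried as a
  start for each subset size (configurable to an evenly spaced subset of
  starts on large grids); ties prefer the smaller subset, then the
  lower-wavelength start.
- *CARS* runs N Monte-Carlo iterations (default 50). The retained-count
  schedule is the exponentially decreasing function
  r_i = round(p·a·e^(−k·i)) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1),
  so r_1 = p and r_N = 2. Each iteration refits the importance model on a
  random 80 % row subsample, keeps the top-r_i bands by normalized
  importance (enforced shrink), and applies adaptive reweighted sampling as
  an importance-weighted draw without replacement within the kept set.
  With the draw made without replacement at exactly the retained count,
  membership is decided by the enforced top-weight cut and the ARS draw
  fixes the subset ordering; the Monte-Carlo variability enters through
  the row subsampling. This keeps subset sizes exactly on the EDF schedule
  and every pool nested in the previous one — both assertable invariants.
  A floor of 1e−12 on the weights lets zero-importance bands participate
  in the draw.

**Classifiers.** RF (bagged CART ensemble; impurity-based feature
importances, normalized to sum to 1, are the band "contribution rates"),
KNN (Euclidean majority vote, k = 5) and RBF-kernel SVM (one-vs-one
multi-class) as comparators. Defaults for the untuned RF: 100 trees,
depth cap 30 (effectively unlimited at these sample sizes), seeded
bootstrap.

**Hyperparameter tuning.** PSO (canonical global-best: w = 0.72,
c1 = c2 = 1.49, 20 particles × 30 iterations) and DE (DE/rand/1/bin,
F = 0.7, CR = 0.9, 20 individuals × 30 generations) maximize a fitness
defined as 5-fold stratified cross-validation accuracy of the RF on the
calibration set. "Training accuracy" protocols that evaluate on the
held-out set during tuning leak information, so CV-on-calibration is the
default here. Search space: n_trees ∈ [10, 500], max_depth ∈ [2, 30],
min_samples_split ∈ [2, 10], max_features_fraction ∈ [0.1, 1.0]. Integer
dimensions are optimized continuously and rounded at evaluation — the
simplest reproducible encoding. Both optimizers seed the default
hyperparameter vector into the initial population, so tuning can never
score below the default on the same fitness, and both record the monotone
best-so-far history. Positions are clipped to bounds.

**Metrics.** Per class: precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2PR/(P+R). Overall accuracy is micro accuracy (confusion-matrix trace
over total), which is also the support-weighted mean of per-class recalls.
Empty denominators yield 0 with a logged warning (they do not arise in
normal runs). Report files round to 4 decimals, the conventional precision
for these tables.

## Synthetic data

No public spectra accompany the study design, so validation runs on a
generative model with known ground truth. Each sample is

    x(λ) = profile_c(λ)·m + b + slope·(λ − λ_mid) + ε(λ)

where profile_c is the class profile (shared smooth continuum plus
class-specific Gaussian features), m ~ LogNormal(0, σ_m) and b ~ N(0, σ_a)
are per-sample affine scatter, slope ~ N(0, σ_slope) is a linear drift, and
ε is band-wise Gaussian noise whose σ is inflated ×5 outside 410–980 nm to
emulate the low-SNR spectral edges. Class counts default to 513 intact /
256 broken / 423 impurity (1192 samples) on the 281-channel grid.

Defaults, chosen once as realistic for seed/grain VNIR reflectance and not
revisited: σ_m = 0.05 (≈5 % multiplicative scatter), σ_a = 0.02 reflectance
units, σ_slope = 10⁻⁴ nm⁻¹, σ_ε = 0.004. Class profiles differ in the depth
of absorption-like features near 680 nm and 925 nm (intact vs broken grain)
while impurities add a 550 nm feature and a steeper continuum — feature
placement follows the wavelength regions that discriminate the classes in
the real-data study, so selection-recovery tests are meaningful.

The affine scatter is *exactly* the model SNV and MSC invert, so
"preprocessing removes scatter" is a testable identity here, not an
empirical claim. Conversely the generator omits real-data features —
nonlinear baselines, correlated (non-white) noise, within-class moisture
and morphology covariates, instrument drift — so passing tests demonstrate
the correctness and internal consistency of the machinery, not field-level
accuracy. The near-separable design (end-to-end RF accuracy ≥ 0.95) is a
property of the generator, intended as a regression surface for the
pipeline, and says nothing about performance on harvested-sample spectra.

## Problem sizes used in tests and the acceptance script

Exhaustive-oracle comparisons run at small scale where the oracle is
tractable: SPA against a dense-projector brute force on 6×5 matrices, SPXY
against an O(n³) re-scanning greedy at n = 8. Selector ground-truth
recovery uses 90-sample, 12-band tables with two discriminative bands over
20 seeded replicates; end-to-end accuracy uses the full default 1192×265
dataset over 10 seeds. The acceptance script runs SPA at subset size 8 with
40 evenly spaced start bands and CARS with the standard 50-iteration
schedule on the full grid. These sizes were chosen to keep the whole
validation cycle fast while leaving every algorithmic path exercised at
full fidelity; all of them are parameters, not limits.

## Known limitations

- SPA with all starts is O(p) model fits per subset size; on grids much
  larger than a few hundred bands use the `starts` cap.
- Savitzky–Golay filtering assumes (approximately) uniform band spacing;
  strongly nonlinear grids should be resampled first.
- CARS's adaptive reweighted sampling, made without replacement at the
  retained count, affects subset order but not membership (see above); a
  with-replacement variant would shrink faster than the EDF schedule and
  break the exact-schedule invariant.
- The SPXY split operates on rows; if multiple ROI spectra derive from the
  same physical sample, group-aware splitting is the caller's
  responsibility.
- Class imbalance is left as-is (no reweighting), matching the reference
  workflow.
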