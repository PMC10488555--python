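# Methods

## Data model

Spectra live on a strictly descending, equally spaced wavenumber grid.
The default instrument grid has 949 points from 11,536 cm⁻¹ at
−8 cm⁻¹ steps, ending at 3,952 cm⁻¹.  The nominal span of such
FT-NIR acquisitions is often quoted with a low end near 3,956 cm⁻¹,
which cannot be reconciled with 949 equally spaced points at 8 cm⁻¹;
we fix the endpoint at 3,952 cm⁻¹ because it makes the grid
arithmetic exact and makes the conventional derivative-trimmed region
11,480–4,008 cm⁻¹ exactly 7 points in from each end (935 variables).
Whether the physical instrument step is exactly 8 cm⁻¹ or the
FT-native ≈7.7 cm⁻¹ is left open; nothing downstream depends on it.

A `SpectralDataset` holds the absorbance matrix, per-sample reference
analyte values (acetic acid %w/v, ethanol %v/v, TSS °Brix, caffeic /
gallic / tannic acid µg/mL), batch labels and a calibration/prediction
role.  CSV I/O stores wavenumber headers as integers in cm⁻¹,
descending; JCAMP-DX reading supports AFFN-encoded single spectra
only (compressed SQZ/DIF/DUP ordinates are rejected explicitly).

## Preprocessing

Three per-spectrum variants: none, SNV (center, divide by the n−1
standard deviation), and Savitzky–Golay second derivative (window 7,
polynomial order 2).  Two deliberate conventions:

* **Derivative scale.**  The derivative is taken with respect to point
  index, not cm⁻¹.  Packages differ here; any constant rescaling of
  the X block is absorbed by PLS, so model statistics are unaffected.
* **Edge handling.**  After the derivative, 7 points are dropped at
  each grid end, although the 7-point filter only leaves
  (window−1)/2 = 3 edge points unsupported.  The extra 4 per end are a
  dialect trim that reproduces the conventional 949 → 935 variable
  count for the 11,480–4,008 cm⁻¹ region; we reproduce the count, not
  the (unknown) mechanism of the software that established it.

## PLS core

PLS1 by NIPALS with y-deflation on mean-centered data; no X
autoscaling (the common chemometric default for spectra, where the
variables share units).  For a single response NIPALS needs no inner
iteration, and one pass yields the whole coefficient path b(1..K),
which the selection loops exploit.  The LV count is chosen by full
(leave-one-out) cross-validation; `best_lv` is the smallest count
whose RMSECV is within 1e-12 of the minimum.  `max_lvs` defaults to
15 for full-spectrum models and is clamped to n−2 (each LOO fold
trains on n−1 samples) and to p.  Component extraction stops early if
the weight or score norm falls below 1e-14 relative to the data
scale; the coefficient path is padded with the last attainable model.

The LOO loop and the Monte-Carlo coefficient fits are JIT-compiled
(numba) with a pure-numpy fallback that is verified equivalent in the
test suite to ~1e-14.

## SCARS

Stability of variable j over M Monte-Carlo PLS fits:
c_j = |mean(b_j)| / sd(b_j) (n−1 sd).  A coefficient that never varies
but is nonzero gets c_j = +∞ (maximally stable, always kept);
identically zero gives c_j = 0 (never sampled).

* **Retention schedule.**  r_i = a·e^(−k·i) pinned to retain all p
  variables at iteration 1 and 2 at iteration N (k = ln(p/2)/(N−1));
  counts rounded, clamped to ≥ 2, forced non-increasing.  Because
  iteration 1 evaluates the full spectrum, a run's best RMSECV can
  never exceed the full-spectrum RMSECV of the same data.
* **Two-stage cut.**  The schedule does not fix how the enforced cut
  and the reweighted sampling share the work.  We use: enforced cut to
  a competition pool of the top min(p_current, 2·K_i) variables by
  stability, then adaptive reweighted sampling of K_i from that pool.
  Both stages stay meaningful and subset sizes follow the schedule
  exactly.  ARS draws sequentially without replacement with
  probability ∝ stability (realized by exponential sort keys); the
  historical "draw with replacement, deduplicate" variant — which can
  return fewer than K_i variables — is available via
  `ars_with_replacement=True`.
* **Monte-Carlo sampling.**  ⌈0.6·n⌉ calibration samples per fit,
  drawn without replacement.  Inner PLS fits use up to
  min(max_lvs, n_sub−2, p_subset) components; per-iteration subsets
  are scored by LOO-CV with the LV count chosen per subset.
* **(N, M) tuning.**  Every grid pair is run `nm_repetitions` times
  with fresh randomness; the pair with the lowest mean *best* RMSECV
  wins (ties to grid order).  Averaging the final-iteration RMSECV
  instead is available via `mrmsecv_statistic="final"`, since "mean
  RMSECV over repetitions" is ambiguous between the two.
* **Frequency selection.**  Selection counts over `final_runs` runs at
  the tuned (N, M); candidate thresholds are every distinct nonzero
  count, descending.  Each threshold's variable set gets a LOO-tuned
  PLS model scored by RMSEP on the independent prediction set; the
  minimum wins, ties to the higher threshold (smaller subset).
  Thresholds leaving no variables are skipped.
* **Randomness.**  Every run is a pure function of (data, config,
  seed).  Repetitions and final runs draw child generators from the
  parent stream, keeping results independent of execution order.

Reference-scale settings (N, M tuned on {20, 50, 100, 200, 500}, 30
repetitions, 100 final runs) are the defaults.  Two documented
smaller presets keep experiments tractable on one CPU:
`ScarsConfig.reduced()` (grid {20, 50}, 5 repetitions, 20 final runs)
for problems with tens of variables, and `ScarsConfig.screening()`
(fixed N=25, M=12, 5 final runs) for full-grid 949-variable problems.
These are the problem sizes used by the test suite and the acceptance
script.

## Validation statistics

For residuals e = x_ref − y_pred: bias = mean(e),
SEP = √(Σ(e−bias)²/(nₚ−1)), RMSEP = √(Σe²/nₚ), R² the squared Pearson
correlation, giving the identity RMSEP² = ((nₚ−1)/nₚ)·SEP² + bias².
SEC uses the plain 1/n_c denominator on bias-corrected calibration
residuals; the n−LVs−1 in the T_UE formula refers only to the F-test
degrees of freedom, but an ISO-style n−LVs−1 SEC denominator is
exposed via `convention="dof"`.  Acceptance is strict:
SEP < T_UE = SEC·√F(0.05; nₚ−1, n−LVs−1) and
|bias| < T_b = t(0.975; nₚ−1)·SEP/√nₚ; a statistic exactly at its
limit is rejected.  The bias formula is applied to whichever sample
set is passed (it is used on the prediction set here).  Student/F
quantiles come from scipy's numerical inversions.

## Synthetic data generator

The generator emulates a 28-day two-stage vinegar fermentation
sampled three times a day, with wine added to the fermenter on day 6.

* **Kinetics.**  Logistic segments pinned to endpoint values per
  phase, with an instantaneous jump at wine addition: acetic acid
  0.05 → 1.12 %w/v, dilution dip to 0.39, then rise to 4.17 by day
  28; ethanol 6.5 → 0.46 %v/v, replenished to 5.02, decaying to 0.39;
  TSS 7.97 → 8.30 °Brix, jump to 9.20, rise to 9.80; caffeic
  1.45 → 6.51 and tannic 145 → 200.6 µg/mL rising smoothly; gallic
  5.35 → 4.62 µg/mL nearly flat.  Only endpoint levels and the
  qualitative shape are anchored in reported fermentation behaviour;
  the logistic form is ours.  Per-sample multiplicative jitter
  (1.5 % RSD, the order of the reference methods' precision) and a
  2 % per-batch gain add realistic spread; values are clipped to the
  calibration ranges the trajectories are designed to cover.
* **Spectra.**  Beer–Lambert mixing: water background (strong bands
  at 6,900 and 5,150 cm⁻¹, weaker structure at 8,500/6,000/5,600, a
  broad baseline) plus concentration × Gaussian pure-component bands
  per analyte.  Band centers sit at wavenumbers diagnostic for each
  analyte so that selection experiments have a planted ground truth;
  amplitudes are scaled so each analyte spans ~0.03–0.08 AU over its
  concentration range against a ~1 AU background.
* **Scatter and noise.**  Per-sample multiplicative gain (5 %),
  additive offset (0.02 AU), linear baseline tilt (0.01 AU across the
  grid), emulating turbid-broth transflectance.  Point noise defaults
  to *photometric* scaling: 0.002 AU at zero absorbance, growing as
  10^A (capped at A = 2), because detector noise is roughly constant
  in transmittance and therefore explodes in the near-opaque water
  bands.  A homoscedastic switch (`photometric=False`) exists; with
  scatter and noise disabled the concentration→spectrum map is
  exactly linear.
* **Unmodelled constituents.**  Real broth absorbs through more than
  the six reference-analyzed analytes; the generator includes two by
  default — a "biomass" component following logistic growth with
  fluctuation (standing in for the bacterial population) and a
  "metabolite" pool drifting along a smooth two-harmonic path.  They
  enter the spectra but not the reference table.  Together with
  photometric noise these are what make wavelength selection
  profitable in the simulation, as in practice: a purely linear,
  homoscedastic simulation lets full-spectrum PLS span every nuisance
  direction and selection then has nothing to gain.
* **Study-sized splits.**  Two calibration batches and one independent
  prediction batch, each a full 85-sample run subsampled by uniform
  stride to 81 + 81 / 30 samples; prediction values are clipped into
  the calibration range per analyte (an external validation batch
  chosen inside the calibrated domain).  All outputs are bit-stable
  functions of the seed.

**What passing tests do not show.**  The generator is a band-mixture
model: it has no instrument line-shape, no temperature-driven water
band shifts, no wavelength calibration drift, and its two-component
interference is a caricature of real broth complexity.  Results on it
demonstrate the correctness and the comparative behaviour of the
algorithms under the stated noise structure, not field performance of
any specific calibration.

## Problem sizes and numerical choices

The test suite runs the planted-recovery experiment (3 informative
variables among 50; 20 seeds; reduced tuning settings) and the
full-scale comparison (162/30 samples, 949 variables, 6 analytes,
5 seeds, screening settings) — sizes chosen so the whole suite runs
in minutes on one CPU.  Tolerances: grid spacing constant to 1e-9
relative; SNV moments and CSV round-trips to 1e-12; PLS vs
least-squares to 1e-6 at full rank; stopping thresholds 1e-14
relative.  Degenerate inputs fail loudly (constant spectrum in SNV,
zero-variance y, all-zero stability weights) or are skipped with a
warning (a degenerate SCARS iteration keeps the previous subset).

## Known limitations

* PLS1 only (one response per model); no SIMPLS/kernel variants.
* No automatic outlier removal — an explicit sample-exclusion list in
  the run configuration is the only mechanism.
* JCAMP-DX support is read-only, AFFN-only, single-spectrum.
* The SEC printed-form default (1/n_c) and the two-stage cut pool
  factor (2×) are conventions; both are isolated behind flags or a
  single constant and documented above.
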