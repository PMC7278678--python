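# Methods

`roastcal` implements an inverse-calibration workflow for process mass
spectrometry of coffee roast gas: predicting the roast degree (Colorette,
dimensionless 0–200, lower = darker) and the brew antioxidant capacity
(Folin–Ciocalteu value, gallic-acid-equivalent mg L⁻¹) from unit-mass
soft-ionization mass spectra recorded during roasting. This note documents
the models, the synthetic testbed, the numerical choices, and what the
packaged tests do and do not establish.

## Calibration model

The model is PLS1 inverse calibration: a preprocessed drop spectrum
`x` (one per roast) predicts the property as `ŷ = x·b + ȳ`. PLS1 is
computed with the SIMPLS deflation; score vectors are orthonormal and the
full coefficient path over 1..A latent variables is retained because
cross-validation and CARS consume sub-models heavily. Predictions are
invariant to the PLS variant; the test suite cross-checks them against an
independent NIPALS implementation and, at full rank, against ordinary least
squares.

Assumptions: one drop spectrum per roast enters calibration (the simulator
supports several time points per roast, but the default — and the tested
configuration — is the final 5-s spectrum); descriptors are linear in the
property after the pretreatment chain; reference values carry independent
Gaussian measurement error.

## Pretreatment chain

The order is fixed and enforced: unit-mass binning → 5-s time averaging →
baseline correction → channel exclusion → L1 normalization → mean
centering. Exclusion happens strictly before normalization, so excluded
channels never contribute to the total-intensity denominator.

* **Baseline** — per-channel 10th-percentile subtraction over the roast's
  time axis, clipped at zero. Deterministic, parameter-light, and exact
  (zero) for channels silent before volatile release.
* **Channel exclusion** — m/z 1–58 (only noise under soft ionization),
  caffeine m/z 193–197 (high between-roast variability degrades the
  models; excluded unconditionally), and any channel below its detection
  threshold in more than 5% of the calibration spectra. The threshold is
  3× the per-channel standard deviation over the first 10 s of each roast
  (a blank region before volatile release); the multiplier and the 5%
  fraction are configurable.
* **Noise scalar δx** — the pooled (root-mean-variance) early-window noise,
  expressed on the descriptor scale by dividing the raw early-window rows
  by the median drop-spectrum total over the retained channels. A single
  scalar, because the analytical sensitivity and the LOD range divide by a
  scalar noise. In the simulator the first 10 s are almost signal-free, so
  this is a clean instrument-noise estimate.

## Model selection

* **Monte Carlo CV** — 1000 random 80/20 roast-level splits per component
  count 1..20, re-centered per training subset; squared errors are pooled
  over all holdouts before the root (one pooled RMSE_CV per count, not an
  average of per-repeat RMSEs — fixed for reproducibility).
* **Component count** — argmin of RMSE_CV, ties broken toward fewer
  components. Near-ties within `1e-8` of the curve's spread count as ties
  so that noise-free data of exact rank k selects k instead of an
  arbitrary larger count (beyond the rank the curve is flat at the level
  of floating-point jitter).
* **CARS** — competitive adaptive reweighted sampling: 50 Monte Carlo
  iterations, each fitting PLS on a random 80% of the roasts, ranking
  variables by |b|, force-retaining an exponentially shrinking fraction
  (from all variables down to 2) and drawing the survivors by a
  |b|-weighted bootstrap; each candidate subset is scored by 5-fold
  cross-validation. The whole procedure is repeated 100 times; the final
  mask keeps variables retained in a majority of repetitions (a
  deterministic aggregate, reported alongside the mean ± SD of mask size
  and component count per repetition), and the component count is
  re-selected by Monte Carlo CV on the masked data. CARS's internal
  component cap equals the pre-CARS selection, so refinement can only
  simplify the model.

## Figures of merit

For external validation the explained variance uses the Q²F3 form,
`1 − (RSS_ext/n_ext)/(TSS_cal/n_cal)`, with the total sum of squares about
the calibration mean — insensitive to how the external samples are
distributed. RER is the external range over RMSE_P; RPD (SD_ext/RMSE_P) is
computed but flagged informational since it duplicates R²'s information.
Both range-relative and mean-relative RMSE_P are emitted; neither is
privileged.

Net-analyte-signal quantities project each spectrum onto the regression
vector: `v* = b(bᵀb)⁻¹bᵀv`. SEN_b = 1/‖b‖; SEN_NAS is the calibration
median of ‖v*/cᵢ‖; SEL = 100·‖v*‖/‖v‖ aggregated by the median
(configurable to the mean, matching the median aggregation of SEN_NAS).
ASEN = SEN_b/δx; its inverse is the smallest property difference
distinguishable under instrument noise alone.

The LOD family:

* `LOD_3×RMSEP = 3·RMSE_P`.
* Pseudounivariate: `LOD_pu = 3.3·m_pu·sqrt((1 + h0min + 1/n)·s²_r)` with
  `m_pu` and `s²_r` the slope and residual variance (RSS/(n−2)) of the
  measured-versus-predicted regression and `h0min = ȳ²/Σ(yᵢ−ȳ)²`.
* NAS-based: `LOD_NAS = 3·δx/SEN_NAS` (the same δx as in ASEN — one noise
  scalar throughout).
* Leverage range: `LOD(h₀) = 3.3·sqrt(SEN⁻²var(x)(1+h₀) + h₀·var(y_cal))`
  evaluated at the minimum and maximum zero-property extrapolated
  leverages, with `var(x) = δx²`. `var(y_cal)` is the variance of the
  *reference-value error* (not of the calibration spread); it defaults to
  0, i.e. error-free references, which keeps the whole LOD family at zero
  in the noiseless perfect-fit limit. The extrapolated leverage of sample
  i is `h0ᵢ = (ȳ² + (yᵢ−ȳ)²)/Σ(yⱼ−ȳ)²`, which reduces to `h0min` for a
  sample at the calibration mean; sample-specific LODs evaluate the same
  formula at each `h0ᵢ` and report the median.
* `LOQ = 3·LOD` everywhere.

Residual diagnostics: Shapiro–Wilk normality p-value plus permutation tests
for first- and second-degree polynomial trends of residuals versus
predictions (statistic: R² of the polynomial fit; the residual order is
permuted; default 5000 permutations — a desk-scale count, configurable).

## Target projection

TP score `t = X·b/‖b‖`, loadings `p = Xᵀt/(tᵀt)`: a covariance-based
single-vector summary of which channels carry the property, keeping signal
height. Cross-model correlations align loading vectors on the union of the
models' channel sets with zeros for unselected channels (the alignment is
a package choice); p-values come from the exact t-transform of Pearson r.

## Online prediction and uncertainty

Streaming spectra pass through the persisted preprocessing state and the
masked model; each 5-s spectrum gets the error-in-variable interval

    PrI = ŷ ± t(df, 1−α/2) · sde · sqrt(1 + h + 1/n_cal)

with the leverage `h = t(TᵀT)⁻¹tᵀ` of the new scores against the
calibration score matrix. The radicand is the standard error-in-variable
form. `df` uses cross-validation-based pseudo-degrees of freedom,
`df = n_cal·(RMSE_fit/RMSE_CV)²` (clamped to [1, n_cal−1]), which makes the
df-corrected residual variance equal the cross-validated MSE; consequently
`sde = RMSE_CV`. The classical fallback `df = n − k − 1` is available but
empirically undercovers on the synthetic testbed (mean coverage ≈ 91% vs
≈ 94–95% for the pseudo-df pairing), because the fit residuals of a
latent-variable model understate prediction error. An extrapolation flag is
raised when ŷ leaves the calibration response range or when a spectrum has
no intensity on the retained channels (early roast, before volatile
release — such rows yield NaN predictions).

Coverage caveat: with 67 calibration roasts any residual-scale estimate has
roughly 10% relative sampling error, so coverage conditional on one
campaign fluctuates a few points around the nominal 95%; averaged over
campaigns the intervals are calibrated (the packaged test pools three
campaigns for exactly this reason).

## Synthetic roast-gas generator

A single monotone latent progress `s(t) = clip((t−90 s)/750 s, 0, 1)`
drives compound release and both properties:

* Colorette(s) = 298.3 − 291.7·s + (291.7/15)·softplus(15(s−0.8)):
  strictly decreasing, almost linear early, levelling off toward dark
  roast (range ≈ 170 → 66 over drops between 7 and 14 min).
* FC(s) = 2196 + 2704·s − 2600·s² GA-eq mg L⁻¹: a slight rise to ≈ 2900
  early in the calibrated window, then a steady decrease to ≈ 2300.

Nineteen informative channels (base peak vinylguaiacol m/z 150; its
methyl-loss fragment at m/z 135 tied to 6% of the parent; phenolics,
furans, N-heterocycles, amines; caffeine at m/z 194 with 50% between-roast
RSD) release with profiles built on the basis
`{s, s², s³, s·softplus(15(s−0.8))}`, zero before 90 s. Channel amplitudes
are balanced (a minimal relative adjustment solved at catalogue
construction) so the total ion current over the retained channels is
exactly proportional to `s`; after L1 normalization the drop spectrum is
then an exact affine function of `{s, s², softplus}`, and both property
curves are exactly linear in the noise-free descriptors. The generator
therefore has three latent factors, PLS recovers the mapping exactly at
zero noise, and every downstream stage can be tested against ground truth.
The balancing holds at 248 nm; at 266 nm per-channel response factors
(lower for amines, furans and small N-compounds, higher for substituted
phenolics) break exact linearity, and the amine channel m/z 59 is gated off
entirely. Compounds whose ionization energy exceeds the two-photon energy
`2hc/λ` (9.32 eV at 266 nm, 10.0 eV at 248 nm) carry baseline noise only.

Noise model and defaults: additive Gaussian baseline (SD 0.15 a.u. per
channel per 5-s bin), multiplicative lognormal per channel-time (σ = 5%),
lognormal between-roast amplitude factors (RSD 5%, caffeine 50%), and
Gaussian reference noise (Colorette SD 2.0; FC SD 40 GA-eq mg L⁻¹,
reflecting assay repeatability). The spectral noise levels were fixed so a
default 84-roast campaign yields an external relative prediction error of
4–5% of the calibrated Colorette range — the performance regime of a
well-run roast-gas calibration; they are configuration fields, not fitted
quantities. Campaign drop times are spread evenly over 7–14 min, as in a
designed calibration campaign.

What the generator does **not** emulate: instrument drift and mass-axis
miscalibration, correlated channel noise (beyond the shared L1
denominator), isotope patterns, roast-to-roast temperature-profile
variation, fragmentation physics beyond the fixed m/z 135 : 150 ratio, and
any non-monotone roast progress. Passing tests therefore demonstrate
correctness of the estimators and calibrated uncertainty under the stated
noise model — not robustness to real-instrument artifacts.

## Numerical choices and degenerate inputs

* Rank exhaustion in SIMPLS is detected at a 1e-12 relative score-norm
  threshold; strict fits raise naming the achievable maximum, resampling
  paths pad the coefficient path (components beyond the rank cannot change
  predictions).
* Zero-total spectra are an error in calibration and a flagged NaN in
  streaming; constant responses, zero regression vectors and zero
  reference values raise or skip with a warning as documented per
  function.
* All randomness flows from explicit integer seeds (child seeds below
  2³¹); identical configs rerun bit-identically, and the run manifest
  records the config hash and all seeds.

## Problem sizes used in the packaged checks

Campaigns of 84 roasts (67/17 calibration/external at the 4:1 split),
Monte Carlo CV with 300–1000 repeats, CARS with 20–100 repetitions, and
1000–1200 fresh roasts for interval-coverage estimation. The full default
pipeline (84 roasts, 1000 CV repeats, 100 CARS repetitions, two
properties) runs in well under a minute on one CPU.

## Known limitations

* The 5% channel-exclusion rule uses a 3σ early-window threshold; with
  real data the blank region must actually be blank.
* `var(y_cal)` in the LOD range is not estimable from a single campaign
  without reference replicates; it is an input, defaulting to zero.
* The majority-vote CARS mask can in principle be empty (an error is
  raised); in practice informative channels win comfortably.
* Streaming baseline correction uses the percentile over the spectra seen
  in the file — an offline emulation; a true real-time deployment would
  freeze the baseline from the blank region.
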