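# Methods

This note records the models, the defaults and the design choices behind
`ftirquant`, and what the synthetic data can and cannot show.

## The calibration problem

A mixture of two powdered botanical components is measured by ATR-FTIR in
absorbance mode over 400–4000 cm⁻¹. The response of interest is the
adulterant weight fraction *y* in % w/w (0–100 scale, so all RMSE-type
metrics are in percentage points). Under the Beer–Lambert assumption the
clean absorbance of a mixture at fraction *c* is the convex combination

    x(c) = (c/100) · x_adulterant + (1 − c/100) · x_target

of the two pure-component spectra. Real measurements add multiplicative and
additive distortions, which is why scatter corrections and derivatives enter
the pipeline.

## Synthetic spectra

Each component is a sum of Gaussian and Lorentzian bands at centers typical
of dried plant powders (a broad O–H envelope near 3300 cm⁻¹; alkyl C–H at
2917/2850; C–O stretches at 1732, 1604, 1371, 1318; CH₂ bending at 1417; a
glycosidic C–O–C band at 1027; a C–H bend at 808 cm⁻¹). The two default
profiles share all centers and differ only in relative amplitudes plus one
adulterant-only Lorentzian shoulder at 1580 cm⁻¹ — so the raw spectra look
alike, as they do for real sibling species, while remaining separable. The
amplitudes are configuration values, not claims about real plant chemistry.

Per sample, the clean mixture receives:

| distortion | default | unit | purpose |
|---|---|---|---|
| multiplicative slope `1+a`, a ~ N(0, 0.02) | 0.02 | — | path-length/contact variation (what MSC/SNV correct) |
| additive offset ~ N(0, 0.005) | 0.005 | AU | detector offset |
| degree-2 polynomial baseline, coeffs ~ N(0, 0.005) | 0.005 | AU | smooth ATR baseline drift (what derivatives remove) |
| white noise ~ N(0, 0.002) | 0.002 | AU | detector noise, ~0.3 % of the maximum absorbance (≈0.7 AU) |

No study characterizes within-level replicate variability for this design,
so replicate scatter is entirely the noise model; the defaults above were
chosen once as typical mid-IR ATR behavior. Randomness flows from one seed
through per-sample `SeedSequence` substreams, so extending a design never
perturbs earlier samples.

The default mixing design is 19 levels (5–95 % step 5) × 10 replicates plus
10 pure samples of each component: 210 spectra. `planted_profiles` builds a
second pair of components that are *identical outside a stated wavenumber
window* (default 1500–1700 cm⁻¹); all between-class variance of noise-free
mixtures then lies inside that window, giving ground truth for wavelength
selection.

What the generator does **not** emulate: ATR penetration-depth dispersion
(band intensities varying as ~1/ν), water-vapor and CO₂ lines, detector
nonlinearity, wavenumber-correlated noise, and real biological variability
between specimens. Passing tests therefore demonstrate algorithmic
correctness and the qualitative selection behavior, not instrument-grade
figures of merit on real powders.

## Axis and I/O conventions

The canonical wavenumber axis is stored descending (4000 → 400 cm⁻¹),
matching spectrometer output; readers normalize ascending files and reorder
columns consistently. The default grid has 7467 points (spacing ≈ 0.482
cm⁻¹); axis length is a parameter everywhere and most tests use a 10×
reduced 747-point grid. JCAMP-DX files are written as 4.24-compatible
single-spectrum `(X++(Y..Y))` AFFN blocks with `YFACTOR` 1e-8 (absorbance
round-trips to ~1e-8).

## Pretreatments

* **SNV** standardizes each spectrum to mean 0, spread 1, using the sample
  (n−1) standard deviation — the common chemometric convention; population
  sd would change numbers slightly, which is why the choice is documented.
* **MSC** regresses each spectrum on a reference (x ≈ a·ref + b) and inverts
  the fit: (x − b)/a. The reference is the mean *calibration* spectrum,
  stored in the fitted preprocessor and reused for test spectra — test-set
  statistics never enter any transform (checked by a one-at-a-time test).
* **Savitzky–Golay derivatives** use a 15-point window and polynomial order
  3 (one order that supports both first and second derivatives); output is
  scaled per cm⁻¹. Edge points (7 at each end) come from scipy's one-sided
  polynomial fits and are flagged on the fitted chain rather than dropped.
* Chains apply scatter correction first, then the derivative, following the
  naming convention "SNV + first derivative"; the nine screening chains are
  {raw} ∪ {MSC, SNV} ∪ {1st, 2nd} ∪ {MSC, SNV}×{1st, 2nd}.

## PLS1 and validation

The regression engine is PLS1 with NIPALS deflation on mean-centered X and
y. No variance scaling: derivative spectra carry meaningful relative
magnitudes, and autoscaling would inflate noise channels. The coefficient
vector **b** is recovered as W(PᵀW)⁻¹q and exposed in centered coordinates;
one pass of the deflation yields the coefficient path for every 1..max
latent variables, which makes cross-validation cheap. If the residual
matrix runs out of rank, later entries of the path repeat the last
attainable model, so CV stays well defined on degenerate (e.g. noise-free
rank-2) problems.

Cross-validation supports leave-one-out and k-fold. k-fold folds are
contiguous blocks of a seeded stratified (by y level) shuffle, so every fold
spans the concentration range. The latent-variable count is the argmin of
RMSECV with ties broken toward fewer components; no 1-SE rule. R² defaults
to 1 − SSE/SST (squared Pearson selectable), and cross-validated R² is
reported alongside calibration R² since sources often leave the definition
ambiguous.

Correctness is anchored to independent oracles in the test suite: LOO
RMSECV against a from-scratch refit loop (1e-10), full-component PLS against
closed-form OLS (1e-6), coefficients against scikit-learn's `PLSRegression`
(scale=False), and SG derivatives against analytic polynomial derivatives.

## Wavelength selection

**MW-PLS.** Every contiguous window of each requested width (stride
configurable, 1 by default) is cross-validated; the lowest RMSECV wins,
ties toward the narrower width then the lower start index. Windows are
scored with their own chosen latent-variable count.

**MC-UVE.** M = 500 Monte-Carlo runs (default) each fit PLS on a random
80 % subsample at a fixed latent-variable count (convention: the
full-spectrum chosen count) and record **b**; stability is
S_j = mean(b_j)/std(b_j) with sample sd. Channels with zero sd get signed
infinite S and a flag rather than silent removal. Two cut-off rules are
offered because the originating description ("deleted by the last
classification performance") is ambiguous for regression:

* *noise_augmented* (default): p artificial noise channels of amplitude
  1e-10·sd(X) are appended before the runs; the cut-off is the largest |S|
  among them — a null distribution for an uninformative variable. On
  pure-noise data this removes essentially everything (<5 % survive).
* *quantile_scan*: the |S| quantiles {50, 60, 70, 80, 90, 95}% plus the
  keep-everything baseline are scanned and the cut-off whose surviving set
  minimizes RMSECV is kept — by construction never worse than no
  elimination under the scanning CV.

**iRF.** The spectrum is fractionated into one centered interval per point
(default width 20, edge intervals truncated and flagged), so the interval
count equals the number of variables. The search starts from Q0 = 10 random
intervals; each of N = 1000 iterations draws a candidate subset size from
N(Q, 0.3·Q), forms the candidate by taking the best-ranked intervals (mean
|b| of a PLS fit on the union) from the current subset plus fresh random
candidates, and accepts it if its k-fold RMSECV improves, else with
probability 0.1·(RMSECV_current/RMSECV_candidate). Each interval's
probability is its acceptance frequency N_j/N (exact integer ratio). The
final variable set is chosen by ranking intervals by probability (ties to
the lower start index) and taking the RMSECV-minimizing union of the top-k
intervals, ties to smaller k. The search defaults follow common
random-frog practice; all are config-exposed.

Inside all selection loops the default CV is 5-fold (seeded) rather than
LOO, for tractability; final reported models may use LOO.

## Pipeline

The study runs simulate → split → screen → select → final fit → evaluate.

* **Split**: per-level seeded shuffle then alternating assignment, so each
  of the 21 levels (0, 5..95, 100 %) contributes half its replicates to each
  subset — 105 calibration / 105 test under the default design. Pure
  adulterant samples are split like any level by default and can be excluded
  by config.
* **Screening** defaults to the calibration set only (leakage hygiene) with
  a `screen_on_all` flag to score on the whole sample set instead; the
  screening CV defaults to 21-fold, model assessment to LOO — both
  selectable since sources commonly mix the two.
* All stage randomness derives from one study seed through named substreams
  (`simulate`, `split`, `screen`, `mw_pls`, `mc_uve`, `irf`, `final`), so a
  config + seed pair reproduces every number bit-identically; the report
  carries a config hash and a content hash to verify it.

## Problem sizes

The test suite and the acceptance script run the full-resolution
(7467-point) axis only for the full-spectrum LOO recovery check; all
selection-method studies use the 747-point axis, M = 100 Monte-Carlo runs
and N = 200–300 frog iterations. These sizes were chosen as the package's
default desk-scale configuration; every size is a parameter, and the
full-resolution, full-iteration settings are a config change away.

## Known limitations

* PLS1 only (single response); no PLS2, kernel PLS, or prediction
  intervals.
* No classification mode: the package quantifies the adulterant fraction;
  authentic-vs-adulterated discrimination is a thresholding decision left
  to the user.
* The MW-PLS scan is exhaustive and O(widths × p) cross-validations; on the
  full 7467-point axis with stride 1 it is the slowest stage by far.
* Spectral resampling between mismatched axes is out of scope; JCAMP files
  in one directory must share an axis.
* The synthetic generator's realism limits are listed above; none of the
  reported synthetic figures of merit transfer to real instruments.
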