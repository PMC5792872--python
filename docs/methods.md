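# Methods

## Scope and model

`nirtrace` implements a traceability workflow for NIR diffuse-reflectance
spectra of sea cucumber body wall: given an absorbance matrix **X** (m
samples × n wavelengths) and reference total fat contents **y** (%), it
builds (i) a PLS1 calibration for fat, (ii) a set of fat-informative
wavelength regions by ordered predictor selection, and (iii) a two-step
class-modeling classifier for nine geographic origins.  A synthetic study
generator supplies data with the statistical structure the analysis assumes;
no real spectra ship with the package.

## Spectra and working window

Spectra live on a uniform 2 nm grid from 800–2500 nm.  Analyses run on the
1000–1798 nm window: below 1000 nm and above 1800 nm the generator (like the
instrument class it mimics) produces strongly inflated noise
(`edge_noise_multiplier`, default 8×), so those regions are excluded before
any modelling.  Wavelength regions are closed intervals; a grid point on a
boundary belongs to the region, because published band tables list touching
endpoints that must not drop points.

## Preprocessing

Savitzky–Golay filtering uses a 17-point window and cubic polynomial by
default; derivatives are fused smooth-and-differentiate filters (`deriv` is
taken with respect to wavelength, scaled by the grid step).  The half window
at each edge is truncated rather than extrapolated, so the grid shrinks by
`window − 1` points: fabricated edge values must not enter downstream models.
SNV divides the centred spectrum by its sample (n−1) standard deviation; VN
by the Euclidean norm of the centred spectrum; MSC inverts a per-spectrum
ordinary-least-squares affine fit against a reference spectrum, which
defaults to the calibration-set mean and is frozen by `PreprocessSpec.fit`
so the test set is corrected without leakage.  Named presets: `SG17-SD`
(second derivative), `SD+VN`, `FD`, `SNV`, `MSC`, `VN`.

## PLS and validation

PLS1 is a sequential-deflation (NIPALS) implementation.  With a single
response the weight vector of each latent variable is the normalized
covariance direction `X'y`, so fitting is non-iterative and fully
deterministic.  One decomposition to `l_max` yields the nested regression
vectors of every smaller model, which makes the leave-one-out RMSECV curve
one decomposition per left-out sample.  `l` is chosen as the smallest value
whose RMSECV is within 1e-12 of the minimum (parsimony tie-break);
`l_max` defaults to `min(15, m − 2, n)`.  Reported metrics: RMSECV and RMSEP
are root mean squared leave-one-out / test-set errors in fat-%, and R² is
the squared Pearson correlation between predicted and reference values (so
a constant offset does not reduce it).  `l = rank` reproduces the ordinary
least-squares fit; the test suite checks this against a direct solve and
cross-checks predictions against an independent NIPALS implementation.

## Ordered predictor selection

Wavelengths are ranked by the magnitude of an informative vector — by
default the PLS regression vector, with per-wavelength correlation and their
product as alternatives.  The number of latent variables for the ranking fit
defaults to the LOO-optimal `l` on the full wavelength set ("investigate `l`
first, then build the regression vector"); a fixed ranking `l` tends to be
numerically erratic under strong collinearity.  Nested subsets (sizes
`window`, `window + increment`, …, defaults 20 and 5, ~77 evaluations on the
400-point window) are scored by LOO RMSECV at a fixed `l_eval`.  The
selected subset is the smallest whose RMSECV lies within one standard error
(`1/sqrt(2m)` relative) of the best — RMSECV differences below the
cross-validation noise floor do not distinguish subsets, and plain argmin
over ~80 correlated estimates overfits the selection — capped so the chosen
subset never cross-validates worse than the full set.  Selected indices are
merged into maximal runs of adjacent grid points, reported as closed
regions.  OPS itself contains no randomness.

## Class models, thresholds and selectivity

Each origin gets a class model from its calibration samples:

* **Step I (`pca_md`)** — PCA is fitted on the region-restricted,
  SG17-SD-preprocessed calibration set with a deterministic sign convention;
  class models live on the scores of PC2–PC4 (configurable; PC1 is excluded
  because it carries the dominant bulk-chemistry signal — total fat — rather
  than origin differences).  Distance is Mahalanobis with a per-class score
  covariance shrunk toward its diagonal, `(1−λ)Σ + λ·diag(Σ)`, λ = 0.1,
  because per-class sample sizes (12–25 after the test split) are small for
  a 3-D covariance.
* **Step II (`first_range`)** — spectra are SD+VN-preprocessed, restricted
  to the Step II regions, and min–max anchored on the first (lowest-
  wavelength) selected region; the class model is the mean anchored spectrum
  and the metric is Euclidean.  Anchoring on the first region — which
  contains a fat band — removes each sample's total-fat amplitude, which is
  exactly why this stage can resolve composition differences that Step I
  cannot.

The acceptance threshold of a class is `D_T = max(Hit) + Q·sd(Hit)` with
`Q = 0.25` and the sample (n−1) standard deviation.  `Hit` distances are
jackknifed: each calibration sample's distance is computed against a centre
(and covariance) estimated without it.  In-sample Mahalanobis distances are
bounded by `(n−1)/√n` and systematically understate out-of-sample spread at
these class sizes, which would reject far too many genuine test samples;
jackknifing restores an honest Hit distribution while keeping the formula.

Selectivity between two classes is `S = D / (D_T1 + D_T2)`, where `D` is the
distance between centres — Euclidean for `first_range`, Mahalanobis under
the average of the two class covariances for `pca_md` (which keeps `S`
exactly symmetric).  Classes connected by `S < 1` edges form ambiguity
groups (connected components).

## Two-step routing

All samples are classified by Step I (nearest class by distance).  A sample
is routed to Step II if its assigned class belongs to an ambiguity group or
if its distance to every class exceeds that class's threshold.  Step II
models are fitted only on the calibration samples of the routed group's
classes; a routed sample whose Step I class is not in any group goes to the
single existing group, or stays "unknown" if there is none or Step II also
rejects it.  The correct-classification rate counts "unknown" as incorrect.
With `Q ≥ 0` every calibration sample lies within its own class threshold
only up to the jackknife (hits are out-of-sample by construction), but
calibration assignment is still by nearest class, so calibration rates are
not inflated by thresholding.

## The synthetic study generator

The generator emulates a nine-origin, 189-sample design: per-origin sample
counts (22, 17, 20, 22, 20, 21, 30, 17, 20) and total-fat means ± s.d.
(4.63 ± 0.38 … 5.96 ± 2.34 %) follow the study design; fat is drawn from a
normal truncated to positive values.  A spectrum is

```
baseline + fat · Σ fat-bands + fat · δ_origin · ratio-band
         + (signature + jitter) · non-fat bands,
```

then multiplied by a per-sample gain (1 + ε, ε ~ N(0, 0.003)), shifted by an
additive offset (N(0, 0.05)) and perturbed by heteroscedastic Gaussian noise
(2×10⁻⁴ absorbance inside 1000–1800 nm, 8× outside).  Bands are Gaussians at
the standard functional-group positions: fat (C–H) at 1210, 1395, 1725 and
1762 nm; a C–H combination *composition* band at 1330 nm whose weight δ is an
origin's fatty-acid-profile index; origin-signature bands at 1460 nm
(O–H/amide) and 1550 nm (N–H); and a broad water band at 1940 nm common to
all origins.

Design choices that carry the study's logic:

* **Fat enters linearly** (Beer–Lambert-like mixing) — PLS presumes
  approximate linearity.
* **Reference error, not instrument noise, sets quantitation difficulty.**
  Stored fat labels are the true value plus N(0, 0.30 fat-%) reference-method
  error, the calibrated difficulty at which the test-set targets (R² ≥ 0.90,
  RMSEP ≤ 0.45) sit near the achievable boundary.  Instrument noise can then
  stay at a realistic low level, which is what the identification task needs.
* **The CH/PLD/ZZ cluster overlaps by construction, in a way only Step II
  can resolve.**  The three adjacent sites share every signature weight and
  differ only in the composition index δ (0.30 / 0.45 / 0.60; the six other
  origins carry balancing values between −0.53 and −0.17).  Because the
  1330 nm signal is `fat · δ`, the between-site differences are blurred by
  the within-site fat spread that the study design fixes — Step I's
  Mahalanobis model cannot separate them (S < 1) at any metric scaling —
  while Step II's range anchoring divides the fat amplitude out and reads δ
  directly (S > 1).  This mirrors the use of fatty-acid profiles as origin
  biomarkers.
* **Total fat stays PC1.**  The signature plane is decorrelated from the
  origin fat means, and the composition levels are least-squares balanced so
  that both `E[fat·δ]` and `E[fat²·δ]` vanish over the design; the fat axis
  and the composition axis then remain separate principal components
  (empirically ~72 % and ~18 % of variance, with the signature plane at ~9 %),
  and excluding PC1 removes fat — not origin information — from Step I.
* **Within-site biological variability is bounded**: signature weights are
  jittered uniformly (half-widths 0.15; 0.04 for the composition index).  A
  bounded dominant within-class spread is what makes `max(Hit) + 0.25·sd` a
  reliable threshold; with heavy Gaussian spread the distribution-free
  `P(new > max of n) ≈ 1/(n+1)` would force ~2 spurious rejections per
  45-sample test set at these class sizes.

What the generator does *not* model: real *A. japonicus* band intensities
(none are published), radiative-transfer effects of diffuse reflectance,
individual fatty-acid species, temperature/moisture drifts, or instrument
wavelength error.  Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes — linear fat mixing, additive origin
signatures, fat-multiplied composition differences — not that it would
achieve these numbers on real animals.

## Default run conditions and problem sizes

The default experiment is the full study scale: 189 samples; 148/41 random
split for quantitation; 144/45 (five test samples per origin) for
identification; LOO cross-validation throughout (a k-fold option exists for
OPS but is off by default).  The complete pipeline — generation, OPS with
~77 LOO-scored subsets, final PLS, two-step classification — runs in under
ten seconds on one CPU.  At the default seed both classification rates are
exactly 100 %; across seeds the combined rate is 98–100 %, the residual
being occasional threshold rejections of test samples (the order-statistic
floor discussed above).

## Numerical conventions

Sample standard deviations use n−1 throughout (SNV, S_Dev of hits, score
covariances).  PCA signs follow "largest-magnitude loading element
positive".  Ties in `l` selection break to the smallest `l` (1e-12
tolerance); ties in wavelength ranking break to the lower wavelength index.
`predict` refuses a grid that differs from the training grid rather than
interpolating silently.  Degenerate inputs raise informative errors:
constant spectra (SNV/VN/MSC), flat first region (range scaling), classes
with fewer than two samples, singular unshrunk covariances.
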