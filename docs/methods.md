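# Methods

## Spectral reduction

Raw integrating-sphere radiances are reduced per leaf as

    R(λ) = (sample(λ) − stray(λ)) / (white(λ) − stray(λ)) · panel(λ)

where `white` is the radiance of the white spectralon reference,
`stray` the light-trap signal, and `panel` the manufacturer-certified
absolute reflectance of the panel. A zero reference denominator at any
band raises an error naming the wavelength rather than propagating an
infinity. Leaves of one plant are averaged arithmetically per band.

Spectra are cropped to 400–1800 nm with inclusive endpoints; on a 1 nm
grid this retains exactly 1401 bands. The inclusive-endpoint convention
is forced by that band count.

Smoothing is a second-order Savitzky–Golay filter with two windows: 31
samples for bands at or below 800 nm and 51 samples above. Both filters
are run over the full spectrum and the outputs stitched at 800 nm,
which avoids discontinuities that would arise from filtering the two
segments separately. Window widths quoted in nm are converted to sample
counts assuming a uniform 1 nm grid; non-uniform axes are rejected for
smoothing rather than resampled silently. Edge bands are fitted by
least-squares polynomials over the truncated available window (no
mirror padding), so any polynomial up to the filter order passes
through the filter unchanged everywhere, including the first and last
bands. This property is what the smoothing tests assert (≤1e−9 per band
for quadratics).

Absorbance is derived as A = 1 − R − T on the intersection of plants
with both reflectance and transmittance; plants present in only one
input are dropped and recorded. Values outside [0, 1] (possible when
R + T > 1 through measurement error) are flagged and propagated, never
clamped — clamping would silently distort the PLSR inputs.

## Mask correction

Narrow leaves are measured through a slit mask that contributes to
every signal. The correction is reconstructed as a per-band two-point
affine inversion: with masked and unmasked (true) spectra of a bright
and a dark reference,

    gain = (true_white − true_black) / (masked_white − masked_black)
    offset = true_white − gain · masked_white

maps both references exactly onto their true spectra; a masked leaf
signal is corrected as gain · m + offset. This is the minimal model
consistent with a two-reference calibration and is exactly testable: a
forward-simulated contamination m = (r − o)/g is recovered to machine
precision. Masked measurements showing an abrupt step at the
transitions between the instrument's three internal spectrometers are
flagged (absolute first difference at configured seam wavelengths,
default 1000 and 1800 nm, above 0.05 reflectance units) and excluded.
No geometric model of the mask is attempted.

## Traits

SLA = area/dry mass (mm²/mg), LDMC = 1000·dry/fresh (mg/g),
LNC_area = LNC/SLA — the unit algebra (mg/g)/(mm²/mg) = 1 g/m² holds
without a conversion factor — and likewise LPC_area. The N:P ratio
classifies nutrient limitation: N-limited below 14, P-limited above 16,
colimited between; the boundary values 14 and 16 are assigned to the
colimited class since the limited classes are defined by strict
inequalities. Trait distributions are right-skewed, so the pipeline can
model log-transformed traits; base 10 is used (the base only rescales
coefficients and affects neither r² nor band selection). The
library-level model default is the untransformed trait; the CLI run
config enables log10 by default.

## PLS1 and model selection

The NIPALS sequence for a single response: centre X and y, then per
component a: w ∝ X_aᵀ y_a (normalised), t = X_a w, p = X_aᵀt/tᵀt,
q = y_aᵀt/tᵀt, followed by rank-one deflation of X and y. For one
response the inner iteration converges in a single pass, so the
sequence is applied directly; extraction stops early if the residual
covariance norm falls below 1e−10. Coefficient vectors
β_k = W_k (P_kᵀ W_k)⁻¹ q_k are produced for every k. Bands are centred
but not autoscaled by default (reflectance-type spectra share one
physical scale; autoscaling is a switch). The cap on components is
min(n − 2, 15). With k = rank(X) the coefficients coincide with
ordinary least squares, which the tests verify against the normal
equations; an independent reference PLSR implementation is used in
tests only, as a cross-check.

Leave-one-out validation predicts each plant from a model fitted on the
remaining n − 1, at every component count up to min(cap, n − 3); the
count minimising validation RMSE is selected, ties toward fewer
components. The per-band significance test is a two-sided one-sample
t-test of the LOO fold coefficients against zero (significant when
P < 0.1); zero-variance bands get p = 0 when their common value is
non-zero and p = 1 otherwise. The selection loop crops to the
significant bands, re-selects the component count, and accepts the crop
only when validation RMSE strictly decreases; it stops when all bands
are significant, when no band is significant (all current bands are
retained — reported as `no_improvement`, since cropping to the empty
set cannot improve the validation error), or at a hard iteration cap (default 20). Masks are nested by
construction. The calibration metrics come from a final all-plant refit
on the retained bands at the selected component count.

**Caveat.** LOO fold coefficient vectors are strongly dependent — any
two training sets share all but two plants — so the fold t statistic is
inflated by roughly a factor n relative to a test on independent
refits. Under a pure-noise null only bands whose full-sample
coefficient happens to be within ~t_crit/n of zero are pruned (a few
percent per iteration), and the loop typically reaches
`all_significant` within a handful of iterations having removed only a
small fraction of bands. The procedure is implemented exactly as
stated; its selection is therefore a weak filter rather than calibrated
inference, and the suite asserts reproducibility of the flagged
fraction under a fixed seed rather than a nominal type-I rate. A
consequence is that on synthetic data with one planted feature the
finally retained bands are *not* concentrated near the feature: the
stable coefficients everywhere keep nearly all bands significant.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not leaf biophysics (a radiative-transfer model such as PROSPECT is out
of scope; Gaussian features keep the ground truth analytic and fast).

* Axis: 400–1800 nm at 1 nm (1401 bands).
* Latent constituents per plant (pigment, water, dry matter) drawn from
  a standard normal truncated at ±3.5 sd. Truncation makes the
  bounded-spectra and positive-trait guarantees exact instead of
  probabilistic; within ±3.5 sd the distribution is indistinguishable
  from Gaussian at the sample sizes used.
* Reflectance: a smooth green-leaf continuum (0.22 rising sigmoidally
  by 0.30 across a red edge at 710 nm) minus constituent-weighted
  Gaussian absorption features — defaults pigment 680/40 nm (depth
  0.035), water 1200/50 (0.030) and 1450/60 (0.050), dry matter 1700/80
  (0.035) — plus additive N(0, noise_sd²) noise, default
  noise_sd = 0.005. Transmittance is generated analogously (continuum
  0.16→0.42, 0.8× the feature signal, independent noise) and rescaled
  where R + T would exceed 0.995; absorbance closes the balance exactly,
  A = 1 − R − T.
* Traits: trait = ρ·z_constituent + √(1−ρ²)·ε, affinely placed at
  field-plausible locations (LNC 20 ± 3.5 mg/g tied to pigment, LDMC
  250 ± 45 mg/g tied to dry matter). LPC is LNC divided by an N:P ratio
  drawn at 13.3 ± 6.6 (truncated at 2), which populates all three
  limitation classes; raw masses and areas are generated consistently
  with the derived-trait identities. Default n = 35 plants, ρ = 0.9.
* The recorded truth includes the constituents, the informative-band
  mask (±2 feature widths), and the theoretical validation ceiling ρ².

What the generator does **not** emulate: wavelength-dependent
(heteroscedastic, band-correlated) instrument noise, spectrometer-seam
offsets in unmasked data, non-linear trait–constituent links,
phylogenetic or site structure among plants, and water-vapour artifact
bands. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not performance
on field spectra.

## Problem sizes and numerical choices

Recovery experiments use n = 60 plants at noise_sd = 0.005 with 10
replicates (coupling recovery, median r²_val vs ρ² = 0.81) and 5
replicates per ρ on the decoupling curve {1.0, 0.8, 0.6, 0.4, 0.2};
band-selection summaries use the default n = 35 with a single pigment
feature. These sizes make the full suite and the acceptance script run
in well under a minute each while leaving the medians stable to ±0.05
across seeds. All simulation randomness flows from one explicit integer
seed through named sub-streams; LOO folds are deterministic. Ties in
component selection go to the smaller count; "improved RMSE_val" is
read as a strict decrease (a non-strict reading would loop on
plateaus). Degenerate inputs (constant response, empty crops, zero
reference denominators, axis mismatches) raise informative errors
rather than producing NaNs.

## Known limitations

* The per-band t-test inherits the anti-conservatism discussed above;
  a block bootstrap or independent-split refits would give calibrated
  p-values but is a different procedure from the one specified.
* r²_cal from the final refit is near 1 whenever the selected component
  count is large relative to n; only validation metrics are
  interpretable as accuracy.
* The mask correction assumes a per-band affine contamination; any
  non-linear mask contribution is outside the model.
* The reduction starts from the instrument's averaged radiance per
  measurement; per-reading averaging happens upstream and is not
  modelled.
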