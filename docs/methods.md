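# Methods

This note documents the models, parameter choices and numerical decisions
behind `camoquant`, and what the synthetic-data tests do and do not show
about real photographs.

## Visual modelling

**Pigment templates.** Cone spectral sensitivities are expanded from peak
wavelengths with the standard A1 (rhodopsin) visual-pigment nomogram,
including the β-band, and peak-normalized on the working grid. Only λmax
values are published for the built-in species, so the template choice is a
modelling assumption; A1 is the field default for shallow-water marine
fish. A2/porphyropsin templates and ocular media transmission are out of
scope. Supported λmax range: 330–650 nm.

**Grid and quadrature.** Default wavelength grid 300–700 nm at 1 nm;
quantum catches use trapezoidal integration. At 1 nm the quadrature error
is far below every tolerance used here. Spectra are never extrapolated —
callers must resample explicitly, and resampling outside a spectrum's
support raises.

**Illuminant.** CIE D65, stored as the published relative power table
(10 nm) and converted to photon flux by wavelength weighting before
normalization, because quantum catch counts photons, not energy. Whether
the original toolbox chain integrated photons or energy is not documented;
photon-based is assumed here.

**Observers.** Three built-in visual systems: triplefin (468/517/530 nm,
cone ratio 0.25:1:1, acuity 7 cpd), goby (456/531/553 nm, 0.72:1:0.6,
2.36 cpd), and the dichromatic scorpionfish (455/530 nm, 1:1; used only for
background-vs-background contrasts, so no acuity is defined and the blur is
never applied for it). Viewing distance 30 cm for both image observers.
Receptor noise: Weber fraction ν = 0.05 for the most abundant cone class
and for the luminance channel; scarcer classes scale as
ω_i = ν√(η_max/η_i). The luminance channel is the mean catch of the two
longest-wavelength cones for trichromats; for a dichromat it degenerates to
the single long cone — the only defensible reading for a 2-cone system.

**Contrasts.** Receptor signals are log-linear, Δf_i = ln(q_i^a/q_i^b).
Achromatic contrast is |ln(L_a/L_b)|/ν with ν applied directly (not
abundance-scaled). Chromatic contrast uses the standard RNL closed forms
for 2 and 3 cones; the test suite checks both against an independently
coded general quadratic form (noise-metric projection orthogonal to the
achromatic direction) on thousands of random catch pairs. Thresholds 1 JND
(detection) and 3 JND (conservative) are exported as named constants; the
package reports raw JNDs and does not adjudicate between them.

## Image pipeline

**Normalization.** Two embedded diffuse grey standards (12% and 72%)
determine a per-channel affine map (slope + intercept) from camera-linear
values to reflectance; the fit is exact at the two anchor points by
construction. Regression through the origin is deliberately not used.

**Camera → cone mapping.** A user-supplied linear matrix; real-camera
calibration is hardware-specific and out of scope. The synthetic pathway
uses the identity (channels are already catches). Outputs are floored at
10⁻⁶ so log-domain operations stay defined.

**Acuity blur.** Gaussian kernel whose FWHM equals the observer's minimum
resolvable angle projected into pixels:
px/degree = scale · distance · tan(1°), σ = (px/degree ÷ acuity)/2√(2 ln 2).
The FWHM-matching convention is a choice (the kernel law of the original
tool is not published) and is configurable via the observer's acuity. If
σ < 0.3 px the observer out-resolves the image sampling and the blur is a
warned no-op. Boundary mode is symmetric reflection, which makes the
operator doubly stochastic: channel means are preserved exactly.

**JND-gated smoothing ("simplified RNL ranked filter").** Each pixel is
replaced by the mean of itself and the neighbours within a disk radius
whose chromatic JND to it is below 1. This keeps the original function —
pool perceptually identical pixels, never across supra-threshold edges —
without reproducing the original ranked-substitution algorithm in detail;
output metadata flags it as simplified. Mirror padding keeps the pooling
operator symmetric, so means are preserved exactly whenever the gate passes
everything; when the gate is active (neighbours beyond 1 JND), reweighting
necessarily moves means slightly — that is the filter doing its job.
Uniform images are fixed points; piecewise-constant images with
supra-threshold boundaries pass through unchanged.

**Coordinates.** Row-major, 0-based; bounding boxes half-open
(row0, row1, col0, col1). ROI masks are boolean arrays; the study folder
stores them as uint8 TIFF.

**Time points.** The two adaptation time points (minute 1 and 5) are
averaged per fish × background × observer; a cell missing one time point is
dropped with a log entry rather than half-averaged.

## Fluorescence

Red-channel values on a 0–255 scale. Photos of one fish are equalized to a
common shutter speed by linear scaling (clipped at 255) before counting.
The fluorescent area is the count of body-mask pixels with value ≥ 100:
"below 100" is removed, so a pixel exactly at 100 counts, and the boundary
behaviour is unit-tested. No particle-size or circularity filtering is
applied; area is reported in absolute pixels with an optional cm²
conversion. 16-bit inputs are rescaled to 0–255 before thresholding.

## Kinetics

Proportional change (L_t − L_0)/(L_60 − L_0) is 0 at t = 0 and 1 at
t = 60 s by construction and invariant to affine rescaling of the
luminance axis. Fish with |L_60 − L_0| < 0.001 catch units are excluded as
non-responders before normalization. Summaries are per-time medians and
interquartile ranges; time-to-fraction linearly interpolates the median
curve between the 5 s samples (a nearest-sample mode is also exposed, since
the sampling grid is coarse and both readings are defensible). Values are
reported unclipped so overshoot in non-monotone fish stays visible. If the
median curve never reaches the requested fraction within 60 s the result is
infinity, reported as "> 60 s".

## Effect sizes

**Models.** Long-format trial tables with fixed effects background ×
species × observer (full interaction, treatment coding with fixed level
order: dark_grey / medium_orange / light_grey reference-first) and fish as
a random intercept. Luminance and chromatic contrast add a random slope
over background, falling back to intercept-only with a flag when the slope
fit is singular or fails to converge. Families: Gamma(log) for luminance
and chromatic contrast, Gaussian for hue and achromatic contrast, negative
binomial(log) for fluorescent counts. A Tweedie family for chromatic
contrast is deliberately substituted by Gamma-log: the response is strictly
positive here and the substitution is recorded in output metadata.

**Backend.** Fitting is delegated to glmmTMB through an Rscript
subprocess; Python owns the design matrix and passes numeric columns, so
coefficient meaning never depends on R's contrast defaults. Many datasets
are fitted in one R session because interpreter startup dominates a single
fit. The Gaussian path is cross-checked against statsmodels MixedLM in the
test suite.

**Inference.** "Posterior" draws are multivariate-normal around the ML
estimates with the estimated covariance (no MCMC), 10,000 draws by default,
seeded and reproducible. Effects are reported as the median of per-draw
differences of predicted cell means on the response scale with the central
95% interval (compatibility interval). Main effects averaged over other
factors use equal-cell weighting of predictions on the response scale — the
weighting convention is otherwise unstated, and equal-cell is the
least-surprising choice for a balanced design. p-values are not reported.
Marginal/conditional R² use the latent-scale variance decomposition:
residual variance σ² (Gaussian), trigamma(shape) (Gamma-log) and
ln(1 + 1/μ̄ + 1/θ) (negative binomial-log).

## Synthetic generator

The generator reproduces the *structure* of the experiments, not their
photographs: uniform backgrounds (flat 12% and 72% greys plus a logistic
long-pass "orange" with half-rise 560 nm), an elliptical fish on a uniform
tray with both grey standards in frame, a per-channel affine camera
(gain 0.5–2, offset 0–0.2) that the normalization must invert, fluorescence
frames with an exact number of supra-threshold pixels under randomized
shutter speeds, and exponential-approach trajectories
L(t) = L60 + (L0 − L60)e^(−kt) with species half-times of 10 s and 5 s.
Trajectory noise (sd 0.02 catch units) is applied to the intermediate time
points; the anchor points t = 0 and t = 60 define the normalization and
carry no added noise. Fish skin is modelled as level × mixture of a flat
and a long-pass component, so hue and luminance co-vary across observers
the way a single physical spectrum forces them to.

Default effect magnitudes follow the scales of the study the pipeline is
built for: background luminance responses of +0.017…+0.054 catch units,
hue shifts of order 0.01–0.04, fluorescent-area differences of
1400–4500 pixels, samples of 24 + 18 fish (21 + 16 with fluorescence
photos, 9 + 14 in the kinetics experiment), between-fish intercept sd 0.2
on the log-luminance scale, random background-slope sd 0.05, residual CV
5%. Every generator is a pure function of (config, seed) and emits ground
truth alongside the data.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the pipeline is unbiased and adequately powered
at the study's own design and effect sizes, and that every algebraic step
(normalization, catch conversion, contrasts, counting, exclusion rules) is
exact. It does not exercise real-photograph nuisances: demosaicing and
nonlinearity residuals, inhomogeneous illumination, fish segmentation
error, texture and pattern, or fluorescence spectral bleed-through. Those
belong to the calibration stages explicitly outside this package's scope.

## Problem sizes and determinism

Synthetic trial images default to 96 × 128 px at 10 px/cm (fluorescence
frames 256 × 320 px), large enough that the fish region dwarfs the blur
kernel while keeping a full 42-fish study renderable in seconds. The
coverage check runs 100 replicate studies with 4,000 draws each, batched
into one R session. All randomness flows from explicit seeds;
glmmTMB fits are deterministic given the data.

## Known limitations

- The general-n RNL quadratic form lives in the test suite as an oracle;
  the package's public API exposes only the 2- and 3-cone closed forms.
- The JND-gated filter approximates, not reproduces, the original ranked
  filter; on real noisy photographs the two can differ near edges.
- The negative-binomial R² uses the lognormal delta approximation with the
  observed mean response; for very small means it is rough.
- The effects module requires an R installation with glmmTMB; there is no
  pure-Python fallback for the non-Gaussian families.
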