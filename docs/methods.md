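# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the pipeline. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Stimulus generation

Images are 2D luminance fields on a nominal [0, 1] scale, 309×302 px by
default. The filtering recipe follows the standard psychophysics order:

1. **Mirror padding** (100 px, reflection without duplicating the edge
   pixel) to suppress wrap-around border artefacts in the FFT.
2. **Normalization** to mean 0 / RMS contrast 1 (RMS contrast = population
   standard deviation of luminance about the mean).
3. **Orientation filtering**: the 2D amplitude spectrum is multiplied by a
   wrapped Gaussian over image-plane orientation, σ = 25°, centres 0°–150°
   in 30° steps. The wrap sum is truncated at |k| ≤ 3 copies (truncation
   error < 1e-300 at σ = 25°) and peak-normalized to 1 at the filter centre,
   so "the filter passes its centre orientation fully" is exact. Phase
   spectra are untouched. The DC term passes unchanged (mean luminance is
   re-equalized afterwards anyway).
4. **Orientation convention**: filter labels refer to the orientation of
   retained *image structure* (0° = vertical, 90° = horizontal). Because an
   oriented grating's Fourier energy lies on the perpendicular frequency
   axis, the weight at frequency (fx, fy) is evaluated at atan2(fy, fx), so
   the 90° filter passes gratings whose luminance varies along the vertical
   pixel axis. Verified against single-frequency gratings with analytic
   transmission values.
5. **Crop** back to the face region (pad removed before statistics are
   recomputed, so normalization describes the face, not the padding).
6. **Re-normalization** to the display statistics, mean 0.5 / RMS 0.12.
7. **Clipping** of out-of-range pixels to [0, 1]; the clipped fraction is
   recorded per image first and stays below 3% across the generated set.
8. **Negation** reflects luminance about the equalized mean
   (out = 1 − in), preserving mean and RMS; **inversion** reverses both
   pixel axes. Both are exact involutions and commute.
9. An **elliptical aperture** fitted to the average face (smallest
   axis-aligned ellipse covering pixels deviating > 0.05 from background,
   cosine edge ramp ≈ 6 px) blends each stimulus into mid-grey.

1/f noise masks are generated by shaping white Gaussian noise in the
frequency domain (amplitude ∝ f^−1, DC removed) and normalizing to the same
(0.5, 0.12) statistics.

The synthetic face generator renders a bright head ellipse on mid-grey with
darker horizontal bands (brows, eyes, nose shadow, mouth), lightly smoothed.
It reproduces the one property the analysis depends on — more energy in
horizontal than vertical structure — and, per identity, images differ by a
small seeded jitter of band geometry. It does not emulate photographic
variability (pose, illumination, hair), so image-level results say nothing
about real-photo difficulty; behaviour and images are linked only through
condition labels.

## Trial design

90 blocks × 14 trials; one stimulus type per block; within a block two
trials per orientation filter plus two full-spectrum trials; blocks grouped
in triplets covering the three stimulus types in random order. The pair pool
(30 same-identity pairs — all within-identity image pairs of 10 identities ×
3 images — and 30 different-identity pairs forming a random 2-regular
matching) is replicated across all 21 condition cells, freshly shuffled per
cell. Same pairs always use two *different* images of one identity, so the
task is identity recognition, not image matching.

## Synthetic observers

Equal-variance Gaussian signal detection for the same/different task with
criterion c (default 0): P("same" | same) = Φ(d/2 − c),
P("same" | different) = Φ(−d/2 − c). Expected d′ per condition:

- natural: Gaussian tuning of raw d′ over orientation, evaluated with
  180°-wrapped angular distance;
- inverted / negated: natural minus a Gaussian-tuned *effect* curve;
- full spectrum: a separate scalar per stimulus type (full-spectrum trials
  are excluded from tuning fits).

Negative expected d′ (possible after subtraction) is clamped to 0 for
response generation only; the analysis pipeline never clamps. Response
times are log-normal (median ≈ 900 ms, log-sd 0.35) with a 2% rate of
extreme slow outliers.

Defaults place the effect curves at the published population posterior
means (inversion: 91.52°, 34.06°, 1.11, 1.20; negation: 85.99°, 39.39°,
1.18, 0.53) with between-subject sds of 8° (locations, widths) and 0.25
(amplitudes); subject-level spreads are not published, so these are package
choices. The natural tuning (location 90°, width 50°, peak 1.9, base 1.6)
and full-spectrum d′ (3.6 / 1.0 / 2.1) were calibrated once, by a small
design-time Monte Carlo, so that the grand standard deviation of measured
d′ across subject × condition cells is ≈ 1. With that calibration the
z-normalization step is approximately the identity at the population level
and the generative effect amplitudes are directly interpretable on the
normalized-d′ scale; the width of 50° reflects the broad natural tuning
reported for familiar faces with outline cues available.

## Scoring

- RT outliers: per subject, a single pass flags trials outside
  mean ± 2.5 sd (sample sd); no iteration; zero-variance subjects keep all
  trials. Exclusion precedes counting.
- d′ with the log-linear correction: H = (hits + 0.5)/(n_same + 1),
  F = (FA + 0.5)/(n_diff + 1), d′ = Φ⁻¹(H) − Φ⁻¹(F). The correction's
  standard form adds 0.5 to counts *and* 1 to totals; always finite.
- z-normalization uses one grand mean/sd across all subject × stimulus
  type × filter cells (full spectrum included). A per-condition scope would
  force every condition mean to zero and erase the stimulus-type
  differences the analysis is about; a per-subject scope is available as an
  option.
- The 0° filter row is duplicated at 180° after normalization (the 0°
  measurement enters tuning fits twice, closing the orientation circle);
  the duplication is idempotent.
- Effects are natural-minus-condition differences of normalized d′ per
  subject × orientation, full spectrum excluded.

## Hierarchical Gaussian tuning model

Likelihood: effect value = base + peak·exp(−(θ − loc)²/(2·sd²)) + ε,
ε ~ N(0, σ). The printed form of this equation in the source literature
lacks the minus sign; it is implemented as a decaying Gaussian (a positive
exponent would be unbounded and contradicts the bell-shaped curves it
describes). Each of the four parameters follows
`1 + effect_type + (1 + effect_type | subject)` with treatment coding
(inversion = reference). Random effects: per parameter, a bivariate normal
(intercept, slope) pair with unstructured 2×2 covariance, independent
across parameters. Priors: intercepts N(90, 20), N(35, 20), N(1.5, 1),
N(1.5, 1) for location, width, peak, base; slopes N(0, 20), N(0, 30),
N(0, 1.5), N(0, 1.5); random-effect scales Exponential(0.1) except base
Exponential(0.05); correlations uniform over [−1, 1]; residual σ ~
Exponential(1) (the last two are package choices — the source specifies
neither).

Sampling: a No-U-Turn sampler written for this package (no probabilistic-
programming framework is among the dependencies): multinomial sampling over
doubling trajectories, generalized U-turn criterion, divergence at energy
error > 1000, dual-averaged step size (target acceptance 0.9–0.95) and
windowed diagonal mass-matrix adaptation. The model is sampled on an
unconstrained scale: non-centered random effects, log scales for sds,
atanh for correlations, with analytic gradients. Two implementations exist
and are tested against each other: a readable numpy reference (and a
recursive Python NUTS validated on analytically known posteriors) and a
numba-compiled kernel + iterative transition used by default (~30× faster).
Convergence is assessed with split-Rhat and bulk ESS (arviz) on all
population-level quantities plus the residual sd; a fit with Rhat > 1.01 or
more than 0.1% divergent draws is flagged, never silently accepted.

Known limitations:

- **Degenerate narrow-width mode.** Because the curve is only observed at
  30° spacing, a Gaussian with width ≲ 5° passing between grid points fits
  the data as "base only" and survives as a minor posterior mode. Long
  chains occasionally visit it (flagged by Rhat); at the reduced settings
  used in the tests (4 × 1500 / 500 warmup) chains stay in the dominant
  mode.
- **Width sign.** The width enters only through sd², so its sign is not
  identifiable; posteriors concentrate on the positive branch and summaries
  should be read as |width|.
- **Noise-induced width shrinkage.** At the study conditions (60 trials per
  condition → ≈ 0.45 noise sd per effect-curve point, 7 points, free base),
  posterior means of the width recover ≈ 6–12° below generative truth while
  locations and amplitudes recover well. This is a property of the
  model-plus-measurement process, not of the sampler: with near-noiseless
  curves the same fit recovers widths to ~1°, and the credible intervals
  are calibrated (see below).

Interval utilities: equal-tailed quantile credible intervals (default 89%);
non-overlap of two intervals is the decision rule for a condition
difference. Posterior predictive curves evaluate the Gaussian on the
population-level draws and report the pointwise mean and 89% band.

Calibration: cohorts drawn from the priors and refitted with the same
priors show 89%-interval coverage of the population parameters within the
binomial tolerance of nominal (the simulation-based-calibration test in the
suite; widths compared on the folded |width| scale).

## Stimulus-type comparison model

`normd′ ~ stimulus_type + (stimulus_type | subject)` on per-subject
sensitivity averaged over orientation filters (full spectrum excluded).
Because the model is linear-Gaussian, the subject random effects are
marginalized analytically — each subject's three condition means are
jointly N(Xβ, XΣX′ + σ²I) — leaving 10 parameters sampled with emcee.
Priors mirror the reference ecosystem's defaults: flat on fixed effects,
half-Student-t(3, 0, 2.5) on sd components and σ, uniform over valid
correlation matrices (tanh-transformed off-diagonals with positive-definite
rejection). Predicted condition means and CrIs come from the fixed-effect
draws.

## Correlation analyses

Subject-level tuning-parameter estimates (posterior means by default;
medians available) are correlated between inversion and negation effects
per parameter: Pearson r, two-sided t-test p, 95% Fisher-z interval.
Partial correlations controlling for a third variable use residualization
with n − 3 effective degrees of freedom and fall back (with a warning) to
the plain correlation if the control is degenerate. No multiplicity
correction is applied. With the default generator the inversion and
negation subject effects are drawn independently, so these correlations are
expected to be modest — the near-unity values reported for real faces are a
property of real observers that the synthetic cohort deliberately does not
build in.

## Problem sizes used by the tests and the acceptance script

The tests run the full design (1260 trials/subject, 21 subjects) but reduce
MCMC to 4 chains × 1500 iterations (500 warmup) for the recovery experiment
and 2 × 1500 (700 warmup) across 50 prior-drawn 6-subject cohorts for the
calibration check; these sizes were chosen so the whole suite runs on one
CPU in well under half an hour while leaving Monte-Carlo error small
relative to the tolerances tested.
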