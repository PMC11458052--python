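# oritune

Orientation tuning of familiar-face identity recognition: stimulus
generation, signal-detection scoring, and Bayesian hierarchical
Gaussian tuning-curve modelling.

## The scientific problem

Human face identification relies preferentially on the *horizontal*
orientation content of the face image (the vertical alternation of light and
dark bands — brows, eyes, mouth — concentrates there). Picture-plane
**inversion** (180° rotation) and contrast **negation** (polarity reversal)
both impair identification, and are thought to disrupt, respectively, the
shape and the surface cues to identity. Comparing the *orientation tuning*
of the two impairments asks whether the horizontal range feeds shape
processing, surface processing, or both.

The experimental logic: show orientation-filtered face images (wrapped
Gaussian filters centred on 0°–150° in 30° steps, 0° = vertical) in three
stimulus types (natural, inverted, negated) in a same/different identity
task; score sensitivity d′ per condition; z-normalize; form per-subject
effect curves

```
inversion effect(θ) = normd′_natural(θ) − normd′_inverted(θ)
negation  effect(θ) = normd′_natural(θ) − normd′_negated(θ)
```

and fit each effect type with a hierarchical Gaussian tuning model

```
effect ~ BaseAmplitude + PeakAmplitude · exp(−(θ − PeakLocation)² / (2·StandardDeviation²))
parameter ~ 1 + effect_type + (1 + effect_type | subject)
```

with normal priors on intercepts/slopes, exponential priors on
random-effect scales, and a NUTS sampler. The decision rule is non-overlap
of 89% equal-tailed credible intervals between effect types, per parameter.

This package implements that full analysis pipeline and exercises it on
**synthetic observers with known ground truth**: procedurally generated
face-like images stand in for celebrity photographs, and simulated
equal-variance signal-detection observers (Gaussian orientation tuning of
d′, binomial same/different responses, log-normal response times) stand in
for participants. Every stage — filtering, trial design, scoring, the
hierarchical fit, interval comparisons, subject-level correlations — is
therefore testable end-to-end without any data download.

## Worked example

```python
from oritune import observer, scoring
from oritune.tuning import MCMCConfig, fit_tuning_model

trials = observer.simulate_cohort(n_subjects=21, seed=0)   # 21 x 1260 trials
table, effects = scoring.score_trials(trials)              # d', normd', effect curves
fit = fit_tuning_model(effects, mcmc=MCMCConfig(4, 1500, 500, seed=0))
print(fit.summary().round(2).to_string(index=False))
```

prints (numbers from this exact invocation):

```
effect_type          parameter  median  mean  cri_lower  cri_upper
  inversion      peak_location   91.49 91.49      83.33      99.60
  inversion standard_deviation   23.83 24.31      18.26      31.72
  inversion     peak_amplitude    1.49  1.49       1.20       1.79
  inversion     base_amplitude    1.18  1.18       1.01       1.35
   negation      peak_location   86.38 86.32      76.80      95.98
   negation standard_deviation   23.16 21.96      -0.02      35.11
   negation     peak_amplitude    1.17  1.16       0.82       1.49
   negation     base_amplitude    0.63  0.63       0.39       0.86
```

The cohort was generated with inversion-effect parameters (peak location
91.5°, width 34.1°, peak amplitude 1.11, base amplitude 1.20) and
negation-effect parameters (86.0°, 39.4°, 1.18, 0.53). Reading the output:
both effects peak in the horizontal range near their generative locations;
the base-amplitude credible intervals separate cleanly ([1.01, 1.35] vs
[0.39, 0.86]) — the inversion effect is larger across all orientations —
while the other three parameters' intervals overlap. Widths recover
systematically narrower than the generative values; with 60 trials per
condition the per-point noise on an effect curve is ≈0.45 normalized-d′
units, and fitting a four-parameter Gaussian to seven such points shrinks
the width estimate (see `docs/methods.md`).

A command-line entry point wraps the same steps:

```bash
oritune simulate --subjects 21 --seed 0 --out trials.csv
oritune score --trials trials.csv --out scores.csv --effects effects.csv
oritune fit --effects effects.csv --chains 4 --iter 1500 --warmup 500 --seed 0 --out posterior/
oritune report --posterior posterior/ --out report/
```

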