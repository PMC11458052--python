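"""Synthetic signal-detection observers with known orientation tuning.

Each simulated subject carries a Gaussian orientation tuning of raw d' for
natural stimuli plus Gaussian-tuned inversion and negation *effects* (the
amount subtracted from natural sensitivity in the inverted / negated
conditions), so the ground truth of every downstream stage — scoring,
z-normalization, effect curves, the hierarchical tuning model — is known by
construction.

Responses follow an equal-variance Gaussian signal-detection model for the
same/different task: on same trials P("same") = Phi(d/2 - c), on different
trials P("same") = Phi(-d/2 - c), with criterion c (0 = unbiased).  Response
times are log-normal with occasional extreme outliers.

The default population values place the inversion and negation effect curves
at the published population posterior means, and the natural tuning /
full-spectrum sensitivities are calibrated so that the grand standard
deviation of measured d' across subject x condition cells is approximately 1
(see docs/methods.md): the z-normalization step is then close to the
identity, and generative effect amplitudes are directly interpretable on the
normalized-d' scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from oritune.design import build_pairs, build_schedule
from oritune.tuning import GaussianTuningParams

STIMULUS_TYPES = ("natural", "inverted", "negated")


@dataclass(frozen=True)
class ObserverParams:
    """One simulated subject."""

    subject_id: str
    natural_tuning: GaussianTuningParams
    inversion_effect: GaussianTuningParams
    negation_effect: GaussianTuningParams
    #: raw d' on unfiltered (full spectrum) trials, per stimulus type
    fullspectrum_dprime: dict = field(
        default_factory=lambda: {"natural": 3.6, "inverted": 1.0, "negated": 2.1}
    )
    criterion: float = 0.0
    rt_log_mean: float = 6.8  # log-ms; exp(6.8) ~ 900 ms
    rt_log_sd: float = 0.35
    rt_outlier_rate: float = 0.02


@dataclass(frozen=True)
class PopulationParams:
    """Population means and between-subject sds of the generative model.

    The effect-curve means default to the published population-level
    posterior means; between-subject sds default to small values (8 deg for
    locations and widths, 0.25 for amplitudes) since subject-level spreads
    are not published.
    """

    natural_tuning: GaussianTuningParams = GaussianTuningParams(90.0, 50.0, 1.9, 1.6)
    inversion_effect: GaussianTuningParams = GaussianTuningParams(91.52, 34.06, 1.11, 1.20)
    negation_effect: GaussianTuningParams = GaussianTuningParams(85.99, 39.39, 1.18, 0.53)
    fullspectrum_dprime: dict = field(
        default_factory=lambda: {"natural": 3.6, "inverted": 1.0, "negated": 2.1}
    )
    sd_location: float = 8.0
    sd_width: float = 8.0
    sd_amplitude: float = 0.25
    sd_fullspectrum: float = 0.25
    criterion: float = 0.0
    criterion_sd: float = 0.0
    rt_log_mean: float = 6.8
    rt_log_sd: float = 0.35
    rt_outlier_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.sd_location, self.sd_width, self.sd_amplitude,
               self.sd_fullspectrum, self.criterion_sd) < 0:
            raise ValueError("between-subject sds must be >= 0")


def _draw_tuning(mean: GaussianTuningParams, pop: PopulationParams,
                 rng: np.random.Generator) -> GaussianTuningParams:
    """Normal draws around the population means, truncated to valid values."""
    loc = mean.peak_location + pop.sd_location * rng.standard_normal()
    for _ in range(100):
        width = mean.standard_deviation + pop.sd_width * rng.standard_normal()
        if width > 1.0:
            break
    else:
        width = 1.0
    for _ in range(100):
        peak = mean.peak_amplitude + pop.sd_amplitude * rng.standard_normal()
        if peak >= 0.0:
            break
    else:
        peak = 0.0
    base = mean.base_amplitude + pop.sd_amplitude * rng.standard_normal()
    return GaussianTuningParams(loc % 180.0, width, peak, base)


def draw_observers(pop: PopulationParams, n_subjects: int = 21, seed: int = 0) -> list[ObserverParams]:
    """Draw a cohort of observers; deterministic given the seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for s in range(n_subjects):
        fs = {
            st: pop.fullspectrum_dprime[st] + pop.sd_fullspectrum * rng.standard_normal()
            for st in STIMULUS_TYPES
        }
        cohort.append(
            ObserverParams(
                subject_id=f"s{s + 1:02d}",
                natural_tuning=_draw_tuning(pop.natural_tuning, pop, rng),
                inversion_effect=_draw_tuning(pop.inversion_effect, pop, rng),
                negation_effect=_draw_tuning(pop.negation_effect, pop, rng),
                fullspectrum_dprime=fs,
                criterion=pop.criterion + pop.criterion_sd * rng.standard_normal(),
                rt_log_mean=pop.rt_log_mean,
                rt_log_sd=pop.rt_log_sd,
                rt_outlier_rate=pop.rt_outlier_rate,
            )
        )
    return cohort


def _wrapped_gaussian(theta_deg: float, params: GaussianTuningParams) -> float:
    """Tuning curve evaluated with 180-deg wrapped angular distance."""
    d = (theta_deg - params.peak_location + 90.0) % 180.0 - 90.0
    return params.base_amplitude + params.peak_amplitude * float(
        np.exp(-(d**2) / (2.0 * params.standard_deviation**2))
    )


def expected_dprime(obs: ObserverParams, stimulus_type: str, filter_level) -> float:
    """Expected raw d' of an observer in one condition cell (may be < 0).

    ``filter_level`` is an orientation in degrees or the string
    'fullspectrum'.  Inverted / negated sensitivity is the natural tuning
    minus the corresponding Gaussian-tuned effect.
    """
    if stimulus_type not in STIMULUS_TYPES:
        raise ValueError(f"unknown stimulus type {stimulus_type!r}")
    if isinstance(filter_level, str) and filter_level == "fullspectrum":
        return float(obs.fullspectrum_dprime[stimulus_type])
    theta = float(filter_level)
    nat = _wrapped_gaussian(theta, obs.natural_tuning)
    if stimulus_type == "natural":
        return nat
    if stimulus_type == "inverted":
        return nat - _wrapped_gaussian(theta, obs.inversion_effect)
    return nat - _wrapped_gaussian(theta, obs.negation_effect)


def simulate_trials(obs: ObserverParams, schedule: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Simulate same/different responses and RTs for one observer.

    Expected d' is clamped at 0 for response generation only (a negative
    subtraction outcome cannot make responses *anti*-discriminative).
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    d = np.array(
        [
            max(expected_dprime(obs, st, f), 0.0)
            for st, f in zip(out["stimulus_type"], out["filter"])
        ]
    )
    is_same = out["is_same"].to_numpy(dtype=bool)
    p_same = np.where(
        is_same,
        norm.cdf(d / 2.0 - obs.criterion),
        norm.cdf(-d / 2.0 - obs.criterion),
    )
    out["response_same"] = rng.random(len(out)) < p_same
    rt = np.exp(obs.rt_log_mean + obs.rt_log_sd * rng.standard_normal(len(out)))
    outlier = rng.random(len(out)) < obs.rt_outlier_rate
    rt[outlier] = np.exp(obs.rt_log_mean + 5.0 * obs.rt_log_sd)
    out["rt_ms"] = rt
    out["subject"] = obs.subject_id
    return out


def simulate_cohort(
    pop: PopulationParams | None = None,
    n_subjects: int = 21,
    seed: int = 0,
    *,
    n_identities: int = 10,
    images_per_identity: int = 3,
) -> pd.DataFrame:
    """Simulate a full cohort: pairs, schedule and responses per subject."""
    pop = pop or PopulationParams()
    cohort = draw_observers(pop, n_subjects, seed)
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    frames = []
    for obs, ss in zip(cohort, seeds):
        rng = np.random.default_rng(ss)
        pairs = build_pairs(n_identities, images_per_identity, seed=int(rng.integers(2**31)))
        schedule = build_schedule(pairs, seed=int(rng.integers(2**31)), subject_id=obs.subject_id)
        frames.append(simulate_trials(obs, schedule, seed=int(rng.integers(2**31))))
    return pd.concat(frames, ignore_index=True)
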