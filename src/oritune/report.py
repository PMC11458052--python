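"""Subject-level correlation analyses and end-to-end orchestration.

After the hierarchical tuning fit, each subject carries posterior point
estimates of the four Gaussian parameters for both the inversion and the
negation effect.  This module correlates them across subjects (per
parameter), optionally controlling for the natural condition through partial
correlation, and provides the one-call pipeline
simulate -> score -> fit -> report.
"""

from __future__ import annotations

import platform
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from oritune import observer, scoring
from oritune.tuning import (
    EFFECT_TYPES,
    MCMCConfig,
    PARAM_NAMES,
    PriorSpec,
    TuningFit,
    fit_tuning_model,
)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""

    r: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n: int


def pearson_correlation(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Pearson r with two-sided t-test p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired observations")
    r, p = stats.pearsonr(x, y)
    lo, hi = _fisher_ci(r, n, ci_level, df_loss=3)
    return CorrelationResult(float(r), float(p), lo, hi, n)


def _fisher_ci(r: float, n: int, level: float, df_loss: int) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return float(r), float(r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - df_loss)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def partial_correlation(x, y, control, ci_level: float = 0.95) -> CorrelationResult:
    """First-order partial correlation r_{xy.z} via residualization.

    Both variables are residualized on the control; p and CI use n - 3
    effective degrees of freedom.  A zero-variance control falls back to the
    plain correlation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    n = x.size
    if n < 4 or y.size != n or z.size != n:
        raise ValueError("need at least 4 paired observations")
    if z.std() == 0:
        warnings.warn("degenerate control variable; returning plain correlation",
                      RuntimeWarning, stacklevel=2)
        return pearson_correlation(x, y, ci_level)
    zc = np.column_stack([np.ones(n), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    ssx, ssy = np.sum(rx**2), np.sum(ry**2)
    # a variable explained (almost) entirely by the control leaves only
    # numerical noise: its partial correlation is 0 by definition
    if ssx <= 1e-12 * np.sum((x - x.mean()) ** 2) or ssy <= 1e-12 * np.sum(
        (y - y.mean()) ** 2
    ):
        r = 0.0
    else:
        r = float(np.sum(rx * ry) / np.sqrt(ssx * ssy))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    lo, hi = _fisher_ci(r, n, ci_level, df_loss=4)
    return CorrelationResult(r, p, lo, hi, n)


def subject_parameter_correlations(fit: TuningFit, stat: str = "mean") -> pd.DataFrame:
    """Correlate subject-level inversion vs negation tuning parameters.

    One Pearson correlation per Gaussian parameter, computed on the
    per-subject posterior point estimates (means by default).
    """
    est = fit.subject_estimates(stat=stat)
    wide = est.pivot_table(
        index=["parameter", "subject"], columns="effect_type", values="estimate"
    )
    rows = []
    for p in PARAM_NAMES:
        sub = wide.loc[p]
        if len(sub) < 3:
            raise ValueError("need at least 3 subjects")
        res = pearson_correlation(sub["inversion"], sub["negation"])
        rows.append({"parameter": p, **asdict(res)})
    return pd.DataFrame(rows)


def run_all(
    pop: observer.PopulationParams | None = None,
    n_subjects: int = 21,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> dict:
    """Full pipeline on a simulated cohort.

    Returns a dict with the trial table, sensitivity table, effect curves,
    the tuning fit, the parameter correlations and a reproducibility
    manifest.
    """
    pop = pop or observer.PopulationParams()
    mcmc = mcmc or MCMCConfig(seed=seed)
    trials = observer.simulate_cohort(pop, n_subjects=n_subjects, seed=seed)
    table, effects = scoring.score_trials(trials)
    fit = fit_tuning_model(effects, priors=priors, mcmc=mcmc)
    correlations = subject_parameter_correlations(fit)
    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_trials": int(len(trials)),
        "mcmc": asdict(mcmc),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "effect_types": list(EFFECT_TYPES),
    }
    return {
        "trials": trials,
        "sensitivity": table,
        "effects": effects,
        "fit": fit,
        "correlations": correlations,
        "manifest": manifest,
    }


def plot_tuning_fit(fit: TuningFit, effects: pd.DataFrame, path=None):
    """Plot per-orientation mean effects with the posterior tuning curves.

    One panel per effect type: subject-mean effect values (dots, +-1 se)
    with the population posterior-mean Gaussian and its 89% ribbon.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from oritune.tuning import posterior_predict_curve

    grid = np.linspace(0.0, 180.0, 91)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, et, color in zip(axes, EFFECT_TYPES, ("tab:blue", "tab:orange")):
        sub = effects[effects["effect_type"] == et]
        means = sub.groupby("filter_deg")["effect"].mean()
        ses = sub.groupby("filter_deg")["effect"].sem()
        curve = posterior_predict_curve(fit, grid, effect_type=et)
        ax.fill_between(curve["theta_deg"], curve["cri_lower"], curve["cri_upper"],
                        alpha=0.25, color=color, lw=0)
        ax.plot(curve["theta_deg"], curve["mean"], color="black", lw=1.5)
        ax.errorbar(means.index, means, yerr=ses, fmt="o", color=color, ms=4)
        ax.set_title(f"{et} effect")
        ax.set_xlabel("orientation filter (deg)")
        ax.set_xticks([0, 30, 60, 90, 120, 150, 180])
    axes[0].set_ylabel("effect (normalized d')")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
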