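"""Bayesian hierarchical comparison of stimulus types.

Fits ``norm_dprime ~ stimulus_type + (stimulus_type | subject)`` to
per-subject sensitivity averaged across orientation filters (full spectrum
excluded).  Treatment coding with the inverted condition as reference gives a
3-vector of fixed effects; each subject has a correlated 3-dimensional random
effect on the same design.

Because the model is linear-Gaussian, the subject random effects are
marginalized analytically: with X the 3x3 within-subject design, the three
observations of subject s are jointly N(X beta, X Sigma X' + sigma^2 I).
Only the 10 remaining parameters (3 fixed effects, 3 log random-effect sds,
3 correlations, log residual sd) are sampled, with emcee.  Priors mirror the
reference ecosystem's defaults: flat on fixed effects, half-Student-t(3, 0,
2.5) on sd components, uniform over valid correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from oritune.tuning import credible_interval

CONDITIONS = ("inverted", "natural", "negated")  # reference first

# within-subject design: rows = conditions, cols = (intercept, natural, negated)
_X = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])


def _half_t_logpdf(x: np.ndarray, df: float = 3.0, scale: float = 2.5) -> float:
    return float(np.sum(-(df + 1.0) / 2.0 * np.log1p((x / scale) ** 2 / df)))


def _unpack(q: np.ndarray):
    beta = q[:3]
    tau = np.exp(q[3:6])
    rho = np.tanh(q[6:9])
    sigma = np.exp(q[9])
    return beta, tau, rho, sigma


def _correlation_matrix(rho: np.ndarray) -> np.ndarray:
    r = np.eye(3)
    r[0, 1] = r[1, 0] = rho[0]
    r[0, 2] = r[2, 0] = rho[1]
    r[1, 2] = r[2, 1] = rho[2]
    return r


def _log_posterior(q: np.ndarray, y: np.ndarray) -> float:
    """Marginal log posterior; y has shape (n_subjects, 3)."""
    beta, tau, rho, sigma = _unpack(q)
    corr = _correlation_matrix(rho)
    # uniform prior over valid correlation matrices: reject non-PD
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return -np.inf
    cov = (tau[:, None] * corr * tau[None, :])
    v = _X @ cov @ _X.T + sigma**2 * np.eye(3)
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = y - (_X @ beta)[None, :]
    solved = np.linalg.solve(chol, resid.T)
    loglik = -0.5 * float(np.sum(solved**2)) - y.shape[0] * float(
        np.sum(np.log(np.diag(chol)))
    )
    logp = loglik
    logp += _half_t_logpdf(tau) + float(np.sum(q[3:6]))          # Jacobian log tau
    logp += float(np.sum(np.log1p(-(rho**2))))                    # Jacobian tanh
    logp += _half_t_logpdf(np.array([sigma])) + float(q[9])       # Jacobian log sigma
    return logp


@dataclass
class GLMMFit:
    """Posterior of the stimulus-type comparison model."""

    #: fixed-effect draws, (n_draws, 3) in treatment coding
    beta_draws: np.ndarray
    rhat: pd.Series
    ess_bulk: pd.Series
    converged: bool
    cri_level: float = 0.89

    def condition_means(self, level: float | None = None) -> pd.DataFrame:
        """Posterior predicted mean norm_dprime per condition, with CrIs."""
        level = self.cri_level if level is None else level
        means = self.beta_draws @ _X.T  # (draws, 3) in CONDITIONS order
        rows = []
        for ci, cond in enumerate(CONDITIONS):
            lo, hi = credible_interval(means[:, ci], level)
            rows.append(
                {
                    "condition": cond,
                    "mean": float(means[:, ci].mean()),
                    "median": float(np.median(means[:, ci])),
                    "cri_lower": lo,
                    "cri_upper": hi,
                }
            )
        return pd.DataFrame(rows)

    def condition_interval(self, condition: str, level: float | None = None):
        level = self.cri_level if level is None else level
        ci = CONDITIONS.index(condition)
        return credible_interval((self.beta_draws @ _X.T)[:, ci], level)


def average_sensitivity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject norm_dprime averaged over orientation filters.

    Full-spectrum cells and the duplicated 180-deg row are excluded so each
    measured orientation contributes once.
    """
    ori = table[~table["filter"].isin(["fullspectrum", "180"])]
    return (
        ori.groupby(["subject", "stimulus_type"])["norm_dprime"].mean().reset_index()
    )


def fit_stimtype_glmm(
    table: pd.DataFrame,
    *,
    n_steps: int = 3000,
    n_burn: int = 1000,
    n_walkers: int = 40,
    seed: int = 0,
) -> GLMMFit:
    """Fit the hierarchical stimulus-type model to a sensitivity table."""
    import emcee

    avg = average_sensitivity(table)
    wide = avg.pivot(index="subject", columns="stimulus_type", values="norm_dprime")
    for cond in CONDITIONS:
        if cond not in wide.columns or wide[cond].isna().any():
            raise ValueError(f"missing {cond} cells")
    y = wide[list(CONDITIONS)].to_numpy()

    rng = np.random.default_rng(seed)
    ndim = 10
    beta0 = np.linalg.lstsq(_X, y.mean(axis=0), rcond=None)[0]
    center = np.concatenate([beta0, np.log([0.3, 0.3, 0.3]), [0.0, 0.0, 0.0], [np.log(0.3)]])
    p0 = center[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(n_walkers, ndim, _log_posterior, args=(y,))
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, dim)

    # split walkers into 4 pseudo-chains for Rhat/ESS
    groups = np.array_split(np.arange(n_walkers), 4)
    names = ["beta_intercept", "beta_natural", "beta_negated"]
    rhats, esss = [], []
    for k in range(3):
        arr = np.stack([chain[:, g, k].T.reshape(-1) for g in groups])
        rhats.append(float(az.rhat(az.convert_to_dataset(arr))["x"]))
        esss.append(float(az.ess(az.convert_to_dataset(arr))["x"]))
    rhat = pd.Series(rhats, index=names)
    ess = pd.Series(esss, index=names)

    flat = chain.reshape(-1, ndim)
    return GLMMFit(
        beta_draws=flat[:, :3],
        rhat=rhat,
        ess_bulk=ess,
        converged=bool(rhat.max() <= 1.05),
    )
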