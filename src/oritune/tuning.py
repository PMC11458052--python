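"""Bayesian nonlinear hierarchical Gaussian tuning model.

The inversion and negation effects (normalized-d' differences from the
natural condition) are modelled, per subject and orientation filter, as a
Gaussian function of orientation::

    effect ~ BaseAmplitude + PeakAmplitude * exp(-(theta - PeakLocation)^2
                                                 / (2 * StandardDeviation^2))

Each of the four tuning parameters gets its own linear regression::

    parameter ~ 1 + effect_type + (1 + effect_type | subject)

with treatment coding (inversion = reference, negation = slope), a bivariate
normal subject random effect per parameter (unstructured 2x2 covariance,
independent across the four parameters), and a shared Gaussian residual on
the effect values.  Priors follow the published defaults: normal intercepts
and slopes, exponential random-effect scales, uniform correlations, and an
exponential residual scale.

The posterior is sampled with the package's own NUTS implementation
(:mod:`oritune.mcmc`) on the unconstrained parameterization (non-centered
random effects, log scales, atanh correlations) with analytic gradients.
Convergence diagnostics (split-Rhat, bulk ESS) are computed with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from oritune.mcmc import sample_nuts

PARAM_NAMES = ("peak_location", "standard_deviation", "peak_amplitude", "base_amplitude")
EFFECT_TYPES = ("inversion", "negation")
THETA_GRID = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


@dataclass(frozen=True)
class GaussianTuningParams:
    """The four parameters of a Gaussian orientation-tuning curve."""

    peak_location: float
    standard_deviation: float
    peak_amplitude: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.standard_deviation <= 0:
            raise ValueError("standard_deviation must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")


def gaussian_tuning(theta_deg, params: GaussianTuningParams):
    """Evaluate the Gaussian tuning curve at orientation(s) ``theta_deg``.

    Decaying Gaussian: the maximum ``base + peak`` is reached at the peak
    location and the curve tends to ``base`` far from it.
    """
    theta = np.asarray(theta_deg, dtype=float)
    out = params.base_amplitude + params.peak_amplitude * np.exp(
        -((theta - params.peak_location) ** 2) / (2.0 * params.standard_deviation**2)
    )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class ParamPrior:
    """Priors for one tuning parameter's regression."""

    intercept_mean: float
    intercept_sd: float
    slope_sd: float
    ranef_rate: float
    slope_mean: float = 0.0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.slope_sd, self.ranef_rate) <= 0:
            raise ValueError("prior sds and rates must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Published default priors of the hierarchical Gaussian model."""

    peak_location: ParamPrior = ParamPrior(90.0, 20.0, 20.0, 0.1)
    standard_deviation: ParamPrior = ParamPrior(35.0, 20.0, 30.0, 0.1)
    peak_amplitude: ParamPrior = ParamPrior(1.5, 1.0, 1.5, 0.1)
    base_amplitude: ParamPrior = ParamPrior(1.5, 1.0, 1.5, 0.05)
    residual_rate: float = 1.0

    def by_name(self, name: str) -> ParamPrior:
        return getattr(self, name)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; iterations are per chain and include warmup."""

    n_chains: int = 4
    n_iterations: int = 6000
    n_warmup: int = 2000
    seed: int = 0
    target_accept: float = 0.9
    max_depth: int = 10

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be below n_iterations")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")

    @property
    def n_draws(self) -> int:
        return self.n_iterations - self.n_warmup


@dataclass
class FitDiagnostics:
    """Convergence diagnostics of one fit."""

    rhat: pd.Series
    ess_bulk: pd.Series
    n_divergent: int
    n_draws_total: int
    converged: bool


# ---------------------------------------------------------------------------
# model internals: packing, log posterior, analytic gradient
# ---------------------------------------------------------------------------


def _kernel():
    """Cached handle to the numba-compiled log-posterior kernel."""
    global _KERNEL
    if _KERNEL is None:
        from oritune._tuning_kernel import tuning_logp_grad

        _KERNEL = tuning_logp_grad
    return _KERNEL


_KERNEL = None


class _TuningModel:
    """Packed-parameter log posterior for the hierarchical Gaussian model.

    Unconstrained vector layout (P = 4 tuning parameters, S subjects)::

        alpha (P) | beta (P) | z (P, S, 2) | log_tau (P, 2) | eta (P) | log_sigma

    where the per-subject random effects are non-centered,
    ``u = diag(tau) @ L(rho) @ z`` with ``L`` the 2x2 correlation Cholesky,
    ``rho = tanh(eta)``, and ``sigma`` the residual sd.
    """

    P = len(PARAM_NAMES)

    def __init__(self, y: np.ndarray, theta: np.ndarray, priors: PriorSpec):
        # y: (S, 2, I) effect values; theta: (I,) orientation grid
        self.y = y
        self.theta = theta
        self.S = y.shape[0]
        self.I = theta.size
        self.N = y.size
        self.priors = priors
        pp = [priors.by_name(n) for n in PARAM_NAMES]
        self.a_mean = np.array([p.intercept_mean for p in pp])
        self.a_sd = np.array([p.intercept_sd for p in pp])
        self.b_mean = np.array([p.slope_mean for p in pp])
        self.b_sd = np.array([p.slope_sd for p in pp])
        self.ranef_rate = np.array([p.ranef_rate for p in pp])
        self.dim = 2 * self.P + 2 * self.P * self.S + 2 * self.P + self.P + 1

    # -- packing -----------------------------------------------------------

    def unpack(self, q: np.ndarray):
        P, S = self.P, self.S
        i = 0
        alpha = q[i : i + P]; i += P
        beta = q[i : i + P]; i += P
        z = q[i : i + 2 * P * S].reshape(P, S, 2); i += 2 * P * S
        log_tau = q[i : i + 2 * P].reshape(P, 2); i += 2 * P
        eta = q[i : i + P]; i += P
        log_sigma = q[i]
        return alpha, beta, z, log_tau, eta, log_sigma

    def subject_params(self, q: np.ndarray) -> np.ndarray:
        """Per-subject tuning parameter values, shape (P, S, 2=effect type)."""
        alpha, beta, z, log_tau, eta, _ = self.unpack(q)
        tau = np.exp(log_tau)
        rho = np.tanh(eta)
        u0 = tau[:, 0, None] * z[:, :, 0]
        u1 = tau[:, 1, None] * (rho[:, None] * z[:, :, 0] + np.sqrt(1 - rho**2)[:, None] * z[:, :, 1])
        v = np.empty((self.P, self.S, 2))
        v[:, :, 0] = alpha[:, None] + u0
        v[:, :, 1] = alpha[:, None] + beta[:, None] + u0 + u1
        return v

    # -- log posterior and gradient ---------------------------------------

    use_compiled = True

    def logp_and_grad(self, q: np.ndarray):
        if self.use_compiled:
            # the kernel handles off-support points (returns -inf) itself
            return _kernel()(
                q, self.y, self.theta, self.a_mean, self.a_sd,
                self.b_mean, self.b_sd, self.ranef_rate,
                self.priors.residual_rate,
            )
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logp, grad = self._logp_and_grad_impl(q)
        if not (np.isfinite(logp) and np.all(np.isfinite(grad))):
            # off-support excursion (overflowing scales etc.): reject the
            # leapfrog step; NUTS treats this as a divergence
            return -np.inf, np.zeros_like(q)
        return logp, grad

    def _logp_and_grad_impl(self, q: np.ndarray):
        P, S, I = self.P, self.S, self.I
        alpha, beta, z, log_tau, eta, log_sigma = self.unpack(q)
        tau = np.exp(np.clip(log_tau, -300.0, 300.0))
        rho = np.tanh(eta)
        sq = np.sqrt(np.maximum(1.0 - rho**2, 1e-300))
        sigma = np.exp(np.clip(log_sigma, -300.0, 300.0))

        u0 = tau[:, 0, None] * z[:, :, 0]                       # (P, S)
        w = rho[:, None] * z[:, :, 0] + sq[:, None] * z[:, :, 1]
        u1 = tau[:, 1, None] * w                                 # (P, S)

        # v: (P, S, T) with T=2 effect types (treatment coded 0/1)
        v = np.empty((P, S, 2))
        v[:, :, 0] = alpha[:, None] + u0
        v[:, :, 1] = alpha[:, None] + beta[:, None] + u0 + u1

        loc, sd, peak, base = v[0], v[1], v[2], v[3]             # (S, T)
        D = self.theta[None, None, :] - loc[:, :, None]          # (S, T, I)
        sd2 = sd[:, :, None] ** 2
        E = np.exp(-(D**2) / (2.0 * sd2))
        mu = base[:, :, None] + peak[:, :, None] * E
        r = self.y - mu
        inv_s2 = 1.0 / sigma**2

        loglik = -0.5 * inv_s2 * float(np.sum(r**2)) - self.N * log_sigma

        # gradient of loglik wrt the (P, S, T) parameter values
        G = r * inv_s2                                           # dL/dmu
        PE = peak[:, :, None] * E
        g = np.empty((P, S, 2))
        g[0] = np.sum(G * PE * D / sd2, axis=-1)                 # d/d loc
        g[1] = np.sum(G * PE * D**2 / (sd[:, :, None] * sd2), axis=-1)  # d/d sd
        g[2] = np.sum(G * E, axis=-1)                            # d/d peak
        g[3] = np.sum(G, axis=-1)                                # d/d base

        d_alpha = g.sum(axis=(1, 2))
        d_beta = g[:, :, 1].sum(axis=1)
        d_u0 = g.sum(axis=2)                                     # (P, S)
        d_u1 = g[:, :, 1]                                        # (P, S)

        d_z = np.empty_like(z)
        d_z[:, :, 0] = d_u0 * tau[:, 0, None] + d_u1 * tau[:, 1, None] * rho[:, None]
        d_z[:, :, 1] = d_u1 * tau[:, 1, None] * sq[:, None]
        d_log_tau = np.empty_like(log_tau)
        d_log_tau[:, 0] = np.sum(d_u0 * z[:, :, 0], axis=1) * tau[:, 0]
        d_log_tau[:, 1] = np.sum(d_u1 * w, axis=1) * tau[:, 1]
        d_rho = np.sum(d_u1 * tau[:, 1, None] * (z[:, :, 0] - (rho / sq)[:, None] * z[:, :, 1]), axis=1)
        d_eta = d_rho * (1.0 - rho**2)
        d_log_sigma = inv_s2 * float(np.sum(r**2)) - self.N

        # priors
        logp = loglik
        logp += float(np.sum(-0.5 * ((alpha - self.a_mean) / self.a_sd) ** 2))
        d_alpha = d_alpha - (alpha - self.a_mean) / self.a_sd**2
        logp += float(np.sum(-0.5 * ((beta - self.b_mean) / self.b_sd) ** 2))
        d_beta = d_beta - (beta - self.b_mean) / self.b_sd**2
        logp += float(-0.5 * np.sum(z**2))
        d_z = d_z - z
        # tau ~ Exponential(rate), sampled on log scale (Jacobian log tau)
        logp += float(np.sum(-self.ranef_rate[:, None] * tau + log_tau))
        d_log_tau = d_log_tau - self.ranef_rate[:, None] * tau + 1.0
        # rho ~ Uniform(-1, 1) via eta = atanh(rho); Jacobian log(1 - rho^2)
        logp += float(np.sum(np.log1p(-(rho**2))))
        d_eta = d_eta - 2.0 * rho
        # sigma ~ Exponential(residual_rate) on log scale
        logp += -self.priors.residual_rate * sigma + log_sigma
        d_log_sigma = d_log_sigma - self.priors.residual_rate * sigma + 1.0

        grad = np.concatenate(
            [d_alpha, d_beta, d_z.ravel(), d_log_tau.ravel(), d_eta, [d_log_sigma]]
        )
        return logp, grad

    # -- initialization ----------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        alpha = self.a_mean + 0.1 * self.a_sd * rng.standard_normal(self.P)
        beta = 0.1 * rng.standard_normal(self.P)
        z = 0.1 * rng.standard_normal((self.P, self.S, 2))
        tau0 = np.array([5.0, 5.0, 0.3, 0.3])
        log_tau = np.log(tau0)[:, None] + 0.1 * rng.standard_normal((self.P, 2))
        eta = 0.1 * rng.standard_normal(self.P)
        log_sigma = np.log(0.5) + 0.1 * rng.standard_normal()
        return np.concatenate([alpha, beta, z.ravel(), log_tau.ravel(), eta, [log_sigma]])


def _sample_chain_compiled(
    model: "_TuningModel",
    q0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    seed: int,
    target_accept: float = 0.9,
    max_depth: int = 10,
):
    """One NUTS chain driven through the numba-compiled transition.

    Identical adaptation schedule to :func:`oritune.mcmc.sample_nuts`
    (dual-averaged step size, windowed diagonal mass); only the per-iteration
    tree building runs compiled.  Returns (draws, n_divergent, accept_stats).
    """
    from oritune import mcmc as _mcmc
    from oritune._tuning_kernel import nuts_transition, seed_rng

    args = (model.y, model.theta, model.a_mean, model.a_sd, model.b_mean,
            model.b_sd, model.ranef_rate, model.priors.residual_rate)
    rng = np.random.default_rng(seed)
    seed_rng(int(rng.integers(2**31)))
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = model.logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones_like(q)

    eps = _mcmc._find_initial_step(model.logp_and_grad, q, logp, grad, inv_mass, rng)
    da = _mcmc._DualAveraging(eps, target=target_accept)
    windows = _mcmc._mass_windows(n_warmup)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros_like(q)
    welford_m2 = np.zeros_like(q)

    draws = np.empty((n_draws, q.size))
    accept_stats = np.empty(n_draws)
    n_divergent = 0

    for it in range(n_warmup + n_draws):
        q, logp, grad, accept_stat, _depth, divergent = nuts_transition(
            q, logp, grad, eps, inv_mass, max_depth, *args
        )
        if it < n_warmup:
            eps = da.update(accept_stat)
            if win_idx < len(windows):
                lo, hi = windows[win_idx]
                if lo <= it < hi:
                    welford_n += 1
                    delta = q - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (q - welford_mean)
                if it == hi - 1:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        var = (welford_n / (welford_n + 5.0)) * var + (
                            5.0 / (welford_n + 5.0)
                        ) * 1e-3
                        inv_mass = var
                        eps = _mcmc._find_initial_step(
                            model.logp_and_grad, q, logp, grad, inv_mass, rng
                        )
                        da = _mcmc._DualAveraging(eps, target=target_accept)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            k = it - n_warmup
            draws[k] = q
            accept_stats[k] = accept_stat
            n_divergent += int(divergent)

    return draws, n_divergent, accept_stats


def _effects_to_array(effects: pd.DataFrame):
    """Pivot a long effect-curve table into a dense (S, 2, I) array."""
    required = {"subject", "filter_deg", "effect_type", "effect"}
    missing = required - set(effects.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    subjects = sorted(effects["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    theta = np.array(sorted(effects["filter_deg"].unique()), dtype=float)
    y = np.empty((len(subjects), 2, theta.size))
    wide = effects.set_index(["subject", "effect_type", "filter_deg"])["effect"]
    for si, s in enumerate(subjects):
        for ti, t in enumerate(EFFECT_TYPES):
            try:
                vals = wide.loc[(s, t)].reindex(theta)
            except KeyError as err:
                raise ValueError(f"missing effect type {t!r} for subject {s!r}") from err
            if vals.isna().any():
                raise ValueError(f"missing orientations for subject {s!r}, {t}")
            y[si, ti] = vals.to_numpy()
    return y, theta, subjects


@dataclass
class TuningFit:
    """Posterior of the hierarchical Gaussian tuning model."""

    #: population parameter values per effect type, (chain, draw, P, T)
    population_draws: np.ndarray
    #: subject parameter values, (chain, draw, P, S, T)
    subject_draws: np.ndarray
    #: residual sd draws, (chain, draw)
    sigma_draws: np.ndarray
    subjects: list
    diagnostics: FitDiagnostics
    cri_level: float = 0.89
    raw_draws: np.ndarray = field(default=None, repr=False)

    def _flat_population(self) -> np.ndarray:
        c, d, P, T = self.population_draws.shape
        return self.population_draws.reshape(c * d, P, T)

    def summary(self, level: float | None = None) -> pd.DataFrame:
        """Population-level summaries per effect type and tuning parameter."""
        level = self.cri_level if level is None else level
        flat = self._flat_population()
        rows = []
        for ti, t in enumerate(EFFECT_TYPES):
            for pi, p in enumerate(PARAM_NAMES):
                draws = flat[:, pi, ti]
                lo, hi = credible_interval(draws, level)
                rows.append(
                    {
                        "effect_type": t,
                        "parameter": p,
                        "median": float(np.median(draws)),
                        "mean": float(np.mean(draws)),
                        "cri_lower": lo,
                        "cri_upper": hi,
                    }
                )
        return pd.DataFrame(rows)

    def population_interval(self, effect_type: str, parameter: str, level: float | None = None):
        level = self.cri_level if level is None else level
        ti = EFFECT_TYPES.index(effect_type)
        pi = PARAM_NAMES.index(parameter)
        return credible_interval(self._flat_population()[:, pi, ti], level)

    def subject_estimates(self, stat: str = "mean") -> pd.DataFrame:
        """Per-subject posterior point estimates of the tuning parameters."""
        c, d, P, S, T = self.subject_draws.shape
        flat = self.subject_draws.reshape(c * d, P, S, T)
        point = np.median(flat, axis=0) if stat == "median" else np.mean(flat, axis=0)
        sd = flat.std(axis=0)
        rows = []
        for pi, p in enumerate(PARAM_NAMES):
            for si, s in enumerate(self.subjects):
                for ti, t in enumerate(EFFECT_TYPES):
                    rows.append(
                        {
                            "subject": s,
                            "effect_type": t,
                            "parameter": p,
                            "estimate": float(point[pi, si, ti]),
                            "sd": float(sd[pi, si, ti]),
                        }
                    )
        return pd.DataFrame(rows)


def fit_tuning_model(
    effects: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    *,
    use_compiled: bool = True,
) -> TuningFit:
    """Fit the hierarchical Gaussian tuning model to subject effect curves.

    ``effects`` is a long table with columns subject, filter_deg (0..180,
    full spectrum excluded, 0 deg duplicated at 180), effect_type
    ('inversion' / 'negation') and effect (normalized-d' difference).
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    y, theta, subjects = _effects_to_array(effects)
    model = _TuningModel(y, theta, priors)
    model.use_compiled = use_compiled

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chain_draws, divergences = [], 0
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        q0 = model.initial_point(rng)
        chain_seed = int(rng.integers(2**31))
        if model.use_compiled:
            draws, n_div, _ = _sample_chain_compiled(
                model, q0,
                n_draws=mcmc.n_draws,
                n_warmup=mcmc.n_warmup,
                seed=chain_seed,
                target_accept=mcmc.target_accept,
                max_depth=mcmc.max_depth,
            )
        else:
            draws, diag = sample_nuts(
                model.logp_and_grad,
                q0,
                n_draws=mcmc.n_draws,
                n_warmup=mcmc.n_warmup,
                seed=chain_seed,
                target_accept=mcmc.target_accept,
                max_depth=mcmc.max_depth,
            )
            n_div = diag.n_divergent
        chain_draws.append(draws)
        divergences += n_div
    raw = np.stack(chain_draws)  # (chain, draw, dim)

    # derived quantities
    C, D = raw.shape[:2]
    pop = np.empty((C, D, model.P, 2))
    subj = np.empty((C, D, model.P, model.S, 2))
    sigma = np.empty((C, D))
    for c in range(C):
        for d in range(D):
            alpha, beta, _, _, _, log_sigma = model.unpack(raw[c, d])
            pop[c, d, :, 0] = alpha
            pop[c, d, :, 1] = alpha + beta
            subj[c, d] = model.subject_params(raw[c, d])
            sigma[c, d] = np.exp(log_sigma)

    diagnostics = _diagnostics(pop, sigma, divergences, C * D)
    return TuningFit(
        population_draws=pop,
        subject_draws=subj,
        sigma_draws=sigma,
        subjects=subjects,
        diagnostics=diagnostics,
        raw_draws=raw,
    )


def _diagnostics(pop: np.ndarray, sigma: np.ndarray, divergences: int, n_total: int) -> FitDiagnostics:
    """Split-Rhat and bulk ESS on the population-level quantities."""
    names, rhats, esss = [], [], []
    for ti, t in enumerate(EFFECT_TYPES):
        for pi, p in enumerate(PARAM_NAMES):
            arr = pop[:, :, pi, ti]
            names.append(f"{p}[{t}]")
            rhats.append(float(az.rhat(az.convert_to_dataset(arr))["x"]))
            esss.append(float(az.ess(az.convert_to_dataset(arr))["x"]))
    names.append("sigma_residual")
    rhats.append(float(az.rhat(az.convert_to_dataset(sigma))["x"]))
    esss.append(float(az.ess(az.convert_to_dataset(sigma))["x"]))
    rhat = pd.Series(rhats, index=names)
    ess = pd.Series(esss, index=names)
    converged = bool(rhat.max() <= 1.01 and divergences <= 0.001 * n_total)
    if not converged:
        warnings.warn(
            f"possible non-convergence: max Rhat {rhat.max():.3f}, "
            f"{divergences} divergences in {n_total} draws",
            RuntimeWarning,
            stacklevel=3,
        )
    return FitDiagnostics(
        rhat=rhat,
        ess_bulk=ess,
        n_divergent=divergences,
        n_draws_total=n_total,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# interval utilities and posterior predictions
# ---------------------------------------------------------------------------


def credible_interval(draws, level: float = 0.89) -> tuple[float, float]:
    """Equal-tailed quantile credible interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def interval_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff two intervals share at least one point."""
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds out of order")
    return max(a_lo, b_lo) <= min(a_hi, b_hi)


def posterior_predict_curve(
    fit: TuningFit,
    theta_grid=None,
    effect_type: str = "inversion",
    level: float = 0.89,
) -> pd.DataFrame:
    """Population-level posterior tuning curve with a credible ribbon."""
    theta = np.asarray(THETA_GRID if theta_grid is None else theta_grid, dtype=float)
    ti = EFFECT_TYPES.index(effect_type)
    flat = fit._flat_population()[:, :, ti]  # (draws, P)
    loc, sd, peak, base = flat[:, 0], flat[:, 1], flat[:, 2], flat[:, 3]
    curves = base[:, None] + peak[:, None] * np.exp(
        -((theta[None, :] - loc[:, None]) ** 2) / (2.0 * sd[:, None] ** 2)
    )
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(curves, [a, 1.0 - a], axis=0)
    return pd.DataFrame(
        {
            "theta_deg": theta,
            "mean": curves.mean(axis=0),
            "cri_lower": lo,
            "cri_upper": hi,
            "effect_type": effect_type,
        }
    )


def sample_prior_cohort(
    priors: PriorSpec, n_subjects: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Draw population truths from the priors and simulate one cohort.

    Used for simulation-based calibration: the generative process is exactly
    the fitted model, so credible intervals fitted with the same priors must
    cover the drawn truths at their nominal rate.  Returns the effect table
    and a dict of the true population-level parameter values per effect type.
    """
    theta = np.asarray(THETA_GRID)
    pp = [priors.by_name(n) for n in PARAM_NAMES]
    alpha = np.array([rng.normal(p.intercept_mean, p.intercept_sd) for p in pp])
    beta = np.array([rng.normal(p.slope_mean, p.slope_sd) for p in pp])
    tau = np.array([rng.exponential(1.0 / p.ranef_rate, size=2) for p in pp])
    rho = rng.uniform(-1.0, 1.0, size=len(pp))
    sigma = rng.exponential(1.0 / priors.residual_rate)

    rows = []
    for s in range(n_subjects):
        z = rng.standard_normal((len(pp), 2))
        u0 = tau[:, 0] * z[:, 0]
        u1 = tau[:, 1] * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
        for ti, et in enumerate(EFFECT_TYPES):
            v = alpha + ti * beta + u0 + ti * u1
            loc, sd, peak, base = v
            mu = base + peak * np.exp(-((theta - loc) ** 2) / (2.0 * sd**2))
            y = mu + sigma * rng.standard_normal(theta.size)
            rows.extend(
                {
                    "subject": f"s{s:02d}",
                    "filter_deg": float(t),
                    "effect_type": et,
                    "effect": float(val),
                }
                for t, val in zip(theta, y)
            )
    truth = {
        "inversion": dict(zip(PARAM_NAMES, alpha)),
        "negation": dict(zip(PARAM_NAMES, alpha + beta)),
    }
    return pd.DataFrame(rows), truth
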