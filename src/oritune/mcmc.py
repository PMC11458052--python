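"""A compact No-U-Turn sampler with dual-averaging step-size adaptation.

Gradient-based MCMC for the hierarchical models in :mod:`oritune.tuning`.
The implementation follows the standard recipe: leapfrog integration with a
diagonal mass matrix, multiplicative tree doubling with multinomial sampling
across the trajectory, the generalized no-U-turn criterion evaluated in
velocity space, dual averaging of the step size toward a target acceptance
statistic during warmup, and windowed estimation of the diagonal mass matrix
from warmup draws (expanding windows, Stan-style).

The only interface a model must provide is ``logp_and_grad(q) -> (float,
ndarray)`` for the log posterior density (up to a constant) on an
unconstrained parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NUTSDiagnostics", "sample_nuts"]

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class NUTSDiagnostics:
    """Per-chain sampling diagnostics."""

    step_size: float
    n_divergent: int
    accept_stats: np.ndarray
    tree_depths: np.ndarray
    inv_mass: np.ndarray = field(default=None)


class _Tree:
    """State of one side of a doubling trajectory."""

    __slots__ = (
        "q_minus", "p_minus", "grad_minus",
        "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop",
        "log_weight", "sum_p", "n_divergent", "stop",
        "sum_accept", "n_accept",
    )


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_and_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _is_uturn(q_plus, q_minus, p_plus, p_minus, inv_mass):
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _nuts_step(logp_and_grad, q0, logp0, grad0, eps, inv_mass, rng, max_depth):
    """One NUTS transition; returns (q, logp, grad, accept_stat, depth, divergent)."""
    p0 = rng.standard_normal(q0.shape) / np.sqrt(inv_mass)
    h0 = logp0 - _kinetic(p0, inv_mass)

    q_minus = q_plus = q0
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad0
    q_prop, logp_prop, grad_prop = q0, logp0, grad0
    log_weight_total = 0.0  # log sum of exp(H - H0) over the trajectory, rel. start
    sum_p = p0.copy()
    sum_accept = 0.0
    n_accept = 0
    divergent = False
    depth = 0

    while depth < max_depth:
        go_right = rng.random() < 0.5
        if go_right:
            sub = _build_tree(
                logp_and_grad, q_plus, p_plus, grad_plus, +eps, depth, h0, inv_mass, rng
            )
            if sub is not None:
                q_plus, p_plus, grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(
                logp_and_grad, q_minus, p_minus, grad_minus, -eps, depth, h0, inv_mass, rng
            )
            if sub is not None:
                q_minus, p_minus, grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus
        if sub is None:
            break  # subtree hit an internal U-turn: stop doubling, discard it
        sum_accept += sub.sum_accept
        n_accept += sub.n_accept
        if sub.n_divergent:
            divergent = True
            break
        if sub.stop:
            break
        # multinomial sampling: accept subtree proposal with prob w_sub / w_total
        if np.log(rng.random()) < sub.log_weight - log_weight_total:
            q_prop, logp_prop, grad_prop = sub.q_prop, sub.logp_prop, sub.grad_prop
        log_weight_total = np.logaddexp(log_weight_total, sub.log_weight)
        sum_p += sub.sum_p
        depth += 1
        if _is_uturn(q_plus, q_minus, p_plus, p_minus, inv_mass):
            break
        if _is_uturn(q_plus, q_minus, sum_p, sum_p, inv_mass):
            break

    accept_stat = sum_accept / max(n_accept, 1)
    return q_prop, logp_prop, grad_prop, accept_stat, depth, divergent


def _build_tree(logp_and_grad, q, p, grad, eps, depth, h0, inv_mass, rng):
    """Recursively build a subtree of 2**depth leapfrog steps.

    Returns a populated :class:`_Tree`, or None if the subtree hit a
    divergence or an internal U-turn (the caller then stops doubling).
    """
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        delta = h1 - h0
        tree = _Tree()
        tree.q_minus = tree.q_plus = tree.q_prop = q1
        tree.p_minus = tree.p_plus = p1
        tree.grad_minus = tree.grad_plus = tree.grad_prop = grad1
        tree.logp_prop = logp1
        tree.log_weight = delta if np.isfinite(delta) else -np.inf
        tree.sum_p = p1.copy()
        tree.n_divergent = int(not np.isfinite(delta) or delta < -_MAX_DELTA_H)
        tree.stop = tree.n_divergent
        tree.sum_accept = float(min(1.0, np.exp(min(delta, 0.0)))) if np.isfinite(delta) else 0.0
        tree.n_accept = 1
        return tree

    first = _build_tree(logp_and_grad, q, p, grad, eps, depth - 1, h0, inv_mass, rng)
    if first is None or first.stop:
        return first
    if eps > 0:
        second = _build_tree(
            logp_and_grad, first.q_plus, first.p_plus, first.grad_plus,
            eps, depth - 1, h0, inv_mass, rng,
        )
    else:
        second = _build_tree(
            logp_and_grad, first.q_minus, first.p_minus, first.grad_minus,
            eps, depth - 1, h0, inv_mass, rng,
        )
    if second is None:
        first.stop = 1  # inner U-turn: stop doubling, keep first half valid
        return first

    first.sum_accept += second.sum_accept
    first.n_accept += second.n_accept
    if second.n_divergent:
        first.n_divergent = 1
        first.stop = 1
        return first

    if eps > 0:
        first.q_plus, first.p_plus, first.grad_plus = (
            second.q_plus, second.p_plus, second.grad_plus,
        )
    else:
        first.q_minus, first.p_minus, first.grad_minus = (
            second.q_minus, second.p_minus, second.grad_minus,
        )
    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.log(rng.random()) < second.log_weight - total:
        first.q_prop, first.logp_prop, first.grad_prop = (
            second.q_prop, second.logp_prop, second.grad_prop,
        )
    first.log_weight = total
    first.sum_p = first.sum_p + second.sum_p
    if _is_uturn(first.q_plus, first.q_minus, first.p_plus, first.p_minus, inv_mass):
        return None
    return first


def _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng):
    """Heuristic: double/halve eps until the one-step accept prob crosses 0.5."""
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps = eps * 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0, target=0.9, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0

    def update(self, accept_stat):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count**-self.kappa
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self):
        return float(np.exp(self.log_eps_bar))


def _mass_windows(n_warmup):
    """(start, end) of expanding variance-estimation windows within warmup."""
    init = max(int(0.15 * n_warmup), 1)
    term = max(int(0.1 * n_warmup), 1)
    windows = []
    start, size = init, max(int(0.1 * n_warmup), 25)
    while start + size < n_warmup - term:
        end = start + size
        if start + 3 * size >= n_warmup - term:
            end = n_warmup - term  # fold the remainder into the last window
        windows.append((start, end))
        start, size = end, 2 * size
    if not windows:
        windows.append((init, max(n_warmup - term, init + 1)))
    return windows


def sample_nuts(
    logp_and_grad,
    q0,
    n_draws: int,
    n_warmup: int,
    seed: int,
    *,
    target_accept: float = 0.9,
    max_depth: int = 10,
):
    """Run one NUTS chain; returns (draws, NUTSDiagnostics).

    ``draws`` has shape (n_draws, dim) and excludes warmup.  All adaptation
    (step size, diagonal mass) happens during the first ``n_warmup``
    transitions and is frozen afterwards.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones_like(q)

    eps = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target=target_accept)
    windows = _mass_windows(n_warmup)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros_like(q)
    welford_m2 = np.zeros_like(q)

    draws = np.empty((n_draws, q.size))
    accept_stats = np.empty(n_draws)
    tree_depths = np.empty(n_draws, dtype=int)
    n_divergent = 0

    for it in range(n_warmup + n_draws):
        q, logp, grad, accept_stat, depth, divergent = _nuts_step(
            logp_and_grad, q, logp, grad, eps, inv_mass, rng, max_depth
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
                        # regularize toward unit scale as Stan does
                        var = (welford_n / (welford_n + 5.0)) * var + (
                            5.0 / (welford_n + 5.0)
                        ) * 1e-3
                        inv_mass = var
                        eps = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)
                        da = _DualAveraging(eps, target=target_accept)
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
            tree_depths[k] = depth
            n_divergent += int(divergent)

    diag = NUTSDiagnostics(
        step_size=eps,
        n_divergent=n_divergent,
        accept_stats=accept_stats,
        tree_depths=tree_depths,
        inv_mass=inv_mass,
    )
    return draws, diag
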