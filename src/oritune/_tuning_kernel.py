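"""Compiled log-posterior kernel for the hierarchical Gaussian tuning model.

Numerically identical to ``_TuningModel._logp_and_grad_impl`` (the readable
numpy reference in :mod:`oritune.tuning`); this version is loop-based and
numba-compiled because the sampler evaluates it millions of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P = 4  # peak_location, standard_deviation, peak_amplitude, base_amplitude


@njit(cache=True, fastmath=False)
def tuning_logp_grad(q, y, theta, a_mean, a_sd, b_mean, b_sd, ranef_rate, res_rate):
    S = y.shape[0]
    I = theta.shape[0]
    N = S * 2 * I
    grad = np.zeros_like(q)

    alpha = q[0:P]
    beta = q[P : 2 * P]
    z_off = 2 * P
    lt_off = z_off + 2 * P * S
    eta_off = lt_off + 2 * P
    ls_off = eta_off + P

    log_sigma = min(max(q[ls_off], -300.0), 300.0)
    sigma = np.exp(log_sigma)
    inv_s2 = 1.0 / (sigma * sigma)

    tau = np.empty((P, 2))
    rho = np.empty(P)
    sq = np.empty(P)
    for p in range(P):
        tau[p, 0] = np.exp(min(max(q[lt_off + 2 * p], -300.0), 300.0))
        tau[p, 1] = np.exp(min(max(q[lt_off + 2 * p + 1], -300.0), 300.0))
        rho[p] = np.tanh(q[eta_off + p])
        sq[p] = np.sqrt(max(1.0 - rho[p] * rho[p], 1e-300))

    # subject/effect-type parameter values and likelihood
    logp = 0.0
    sum_r2 = 0.0
    d_v = np.zeros((P, S, 2))  # dL/d v_{p,s,t}
    for s in range(S):
        z0 = np.empty(P)
        z1 = np.empty(P)
        for p in range(P):
            z0[p] = q[z_off + (p * S + s) * 2]
            z1[p] = q[z_off + (p * S + s) * 2 + 1]
        for t in range(2):
            v = np.empty(P)
            for p in range(P):
                u0 = tau[p, 0] * z0[p]
                if t == 0:
                    v[p] = alpha[p] + u0
                else:
                    w = rho[p] * z0[p] + sq[p] * z1[p]
                    v[p] = alpha[p] + beta[p] + u0 + tau[p, 1] * w
            loc, sd, peak, base = v[0], v[1], v[2], v[3]
            sd2 = sd * sd
            for i in range(I):
                D = theta[i] - loc
                E = np.exp(-(D * D) / (2.0 * sd2))
                r = y[s, t, i] - (base + peak * E)
                sum_r2 += r * r
                G = r * inv_s2
                d_v[0, s, t] += G * peak * E * D / sd2
                d_v[1, s, t] += G * peak * E * D * D / (sd * sd2)
                d_v[2, s, t] += G * E
                d_v[3, s, t] += G

    logp += -0.5 * inv_s2 * sum_r2 - N * log_sigma
    d_log_sigma = inv_s2 * sum_r2 - N

    # chain rule back to the unconstrained parameters, plus priors
    for p in range(P):
        d_alpha = 0.0
        d_beta = 0.0
        d_lt0 = 0.0
        d_lt1 = 0.0
        d_rho = 0.0
        for s in range(S):
            g0 = d_v[p, s, 0]
            g1 = d_v[p, s, 1]
            d_u0 = g0 + g1
            d_u1 = g1
            z0 = q[z_off + (p * S + s) * 2]
            z1 = q[z_off + (p * S + s) * 2 + 1]
            w = rho[p] * z0 + sq[p] * z1
            d_alpha += d_u0
            d_beta += g1
            grad[z_off + (p * S + s) * 2] = (
                d_u0 * tau[p, 0] + d_u1 * tau[p, 1] * rho[p] - z0
            )
            grad[z_off + (p * S + s) * 2 + 1] = d_u1 * tau[p, 1] * sq[p] - z1
            d_lt0 += d_u0 * z0
            d_lt1 += d_u1 * w
            d_rho += d_u1 * tau[p, 1] * (z0 - rho[p] / sq[p] * z1)
            logp += -0.5 * (z0 * z0 + z1 * z1)
        # normal priors on intercept and slope
        logp += -0.5 * ((alpha[p] - a_mean[p]) / a_sd[p]) ** 2
        logp += -0.5 * ((beta[p] - b_mean[p]) / b_sd[p]) ** 2
        grad[p] = d_alpha - (alpha[p] - a_mean[p]) / (a_sd[p] * a_sd[p])
        grad[P + p] = d_beta - (beta[p] - b_mean[p]) / (b_sd[p] * b_sd[p])
        # exponential priors on tau (log scale, with Jacobian)
        logp += -ranef_rate[p] * (tau[p, 0] + tau[p, 1])
        logp += q[lt_off + 2 * p] + q[lt_off + 2 * p + 1]
        grad[lt_off + 2 * p] = d_lt0 * tau[p, 0] - ranef_rate[p] * tau[p, 0] + 1.0
        grad[lt_off + 2 * p + 1] = d_lt1 * tau[p, 1] - ranef_rate[p] * tau[p, 1] + 1.0
        # uniform prior on rho via tanh transform
        logp += np.log1p(-(rho[p] * rho[p]))
        grad[eta_off + p] = d_rho * (1.0 - rho[p] * rho[p]) - 2.0 * rho[p]

    # exponential prior on sigma (log scale, with Jacobian)
    logp += -res_rate * sigma + log_sigma
    grad[ls_off] = d_log_sigma - res_rate * sigma + 1.0

    # off-support excursions (overflowing scales etc.) are rejected outright;
    # the sampler treats them as divergent leapfrog steps
    if not np.isfinite(logp):
        return -np.inf, np.zeros_like(q)
    for k in range(grad.shape[0]):
        if not np.isfinite(grad[k]):
            return -np.inf, np.zeros_like(q)
    return logp, grad


# ---------------------------------------------------------------------------
# compiled NUTS transition specialized to this log posterior
#
# Same algorithm as oritune.mcmc (multinomial NUTS, generalized U-turn
# criterion, divergence at energy error 1000), with the doubling tree built
# iteratively (binary-counter merges) instead of recursively so the whole
# transition stays inside compiled code.  Randomness uses numba's internal
# np.random state; seed per chain via seed_rng.
# ---------------------------------------------------------------------------


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=False)
def _leapfrog_k(q, p, grad, eps, inv_mass, y, theta, a_mean, a_sd, b_mean, b_sd,
                ranef_rate, res_rate):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    logp1, grad1 = tuning_logp_grad(q1, y, theta, a_mean, a_sd, b_mean, b_sd,
                                    ranef_rate, res_rate)
    p1 = p1 + 0.5 * eps * grad1
    return q1, p1, logp1, grad1


@njit(cache=True)
def _logaddexp(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


@njit(cache=True, fastmath=False)
def nuts_transition(q0, logp0, grad0, eps, inv_mass, max_depth, y, theta,
                    a_mean, a_sd, b_mean, b_sd, ranef_rate, res_rate):
    """One NUTS transition; returns (q, logp, grad, accept_stat, depth, divergent)."""
    dim = q0.shape[0]
    p0 = np.random.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(p0 * inv_mass * p0)

    qm = q0.copy(); pm = p0.copy(); gm = grad0.copy()
    qp = q0.copy(); pp = p0.copy(); gp = grad0.copy()
    qprop = q0.copy(); lprop = logp0; gprop = grad0.copy()
    logw_total = 0.0
    sum_p = p0.copy()
    sum_acc = 0.0
    n_acc = 0
    divergent = False
    depth = 0

    while depth < max_depth:
        go_right = np.random.random() < 0.5
        if go_right:
            qc = qp.copy(); pc = pp.copy(); gc = gp.copy(); eps_s = eps
        else:
            qc = qm.copy(); pc = pm.copy(); gc = gm.copy(); eps_s = -eps

        n_leaves = 1 << depth
        cap = depth + 2
        sdepth = np.empty(cap, np.int64)
        s_qm = np.empty((cap, dim)); s_pm = np.empty((cap, dim))
        s_qp = np.empty((cap, dim)); s_pp = np.empty((cap, dim))
        s_qpr = np.empty((cap, dim)); s_gpr = np.empty((cap, dim))
        s_sum = np.empty((cap, dim))
        s_logw = np.empty(cap); s_logp = np.empty(cap)
        top = 0
        ok = True
        div_sub = False

        for _leaf in range(n_leaves):
            qc, pc, lp1, gc = _leapfrog_k(qc, pc, gc, eps_s, inv_mass, y, theta,
                                          a_mean, a_sd, b_mean, b_sd,
                                          ranef_rate, res_rate)
            if np.isfinite(lp1):
                h1 = lp1 - 0.5 * np.sum(pc * inv_mass * pc)
            else:
                h1 = -np.inf
            delta = h1 - h0
            n_acc += 1
            if np.isfinite(delta):
                d0 = delta if delta < 0.0 else 0.0
                sum_acc += np.exp(d0)
            if (not np.isfinite(delta)) or delta < -1000.0:
                div_sub = True
                ok = False
                break
            sdepth[top] = 0
            s_qm[top] = qc; s_pm[top] = pc
            s_qp[top] = qc; s_pp[top] = pc
            s_qpr[top] = qc; s_gpr[top] = gc
            s_sum[top] = pc
            s_logw[top] = delta
            s_logp[top] = lp1
            top += 1
            while top >= 2 and sdepth[top - 1] == sdepth[top - 2]:
                i1 = top - 2  # older half
                i2 = top - 1  # newer half
                if eps_s > 0:
                    nqm = s_qm[i1]; npm = s_pm[i1]
                    nqp = s_qp[i2]; npp = s_pp[i2]
                else:
                    nqm = s_qm[i2]; npm = s_pm[i2]
                    nqp = s_qp[i1]; npp = s_pp[i1]
                dq = nqp - nqm
                if (np.sum(dq * inv_mass * npm) < 0.0
                        or np.sum(dq * inv_mass * npp) < 0.0):
                    ok = False
                    break
                tot = _logaddexp(s_logw[i1], s_logw[i2])
                if np.log(np.random.random()) < s_logw[i2] - tot:
                    s_qpr[i1] = s_qpr[i2]
                    s_gpr[i1] = s_gpr[i2]
                    s_logp[i1] = s_logp[i2]
                s_qm[i1] = nqm; s_pm[i1] = npm
                s_qp[i1] = nqp; s_pp[i1] = npp
                s_sum[i1] = s_sum[i1] + s_sum[i2]
                s_logw[i1] = tot
                sdepth[i1] = sdepth[i1] + 1
                top -= 1
            if not ok:
                break

        if div_sub:
            divergent = True
            break
        if not ok:
            break  # inner U-turn: discard the subtree, stop doubling

        # completed subtree sits in slot 0
        if go_right:
            qp = s_qp[0].copy(); pp = s_pp[0].copy(); gp = gc.copy()
        else:
            qm = s_qm[0].copy(); pm = s_pm[0].copy(); gm = gc.copy()
        if np.log(np.random.random()) < s_logw[0] - logw_total:
            qprop = s_qpr[0].copy()
            gprop = s_gpr[0].copy()
            lprop = s_logp[0]
        logw_total = _logaddexp(logw_total, s_logw[0])
        sum_p = sum_p + s_sum[0]
        depth += 1

        dq = qp - qm
        if np.sum(dq * inv_mass * pm) < 0.0 or np.sum(dq * inv_mass * pp) < 0.0:
            break
        if np.sum(dq * inv_mass * sum_p) < 0.0:
            break

    accept_stat = sum_acc / (n_acc if n_acc > 0 else 1)
    return qprop, lprop, gprop, accept_stat, depth, divergent
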