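"""Numba-compiled likelihood kernels shared by fitting, scoring and selection.

Conventions (fixed across the package):

* stimuli 0..3 in the order go_gain, nogo_gain, go_avoid, nogo_avoid
* domain 0 = gain, 1 = loss; action 0 = no-go, 1 = go
* learning-rate array ``eps`` of length 4 indexed ``2*domain + sign`` with
  sign 0 for a non-negative prediction error and 1 for a negative one,
  i.e. [eps_GP, eps_GN, eps_LP, eps_LN]
* ``rho`` of length 2 indexed by domain
* free (transformed-scale) parameter vectors are ordered: learning rates,
  outcome impacts, action bias, Pavlovian weight — with logit-scale learning
  rates and log-scale impacts.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ll_core(eps, rho, bias, pav, use_pav, stim, domain, action, outcome):
    """Log-likelihood of one session under expanded natural-scale parameters.

    Action values Q and stimulus values V start at zero. Only the chosen
    action's Q is updated; V is updated on every trial when the Pavlovian
    term is active.
    """
    q = np.zeros((4, 2))
    v = np.zeros(4)
    ll = 0.0
    for t in range(stim.shape[0]):
        s = stim[t]
        a = action[t]
        d = domain[t]
        w_go = q[s, 1] + bias
        if use_pav:
            w_go = w_go + pav * v[s]
        w_ng = q[s, 0]
        m = w_go if w_go > w_ng else w_ng
        logz = m + np.log(np.exp(w_go - m) + np.exp(w_ng - m))
        if a == 1:
            ll += w_go - logz
        else:
            ll += w_ng - logz
        rr = rho[d] * outcome[t]
        delta = rr - q[s, a]
        si = 0 if delta >= 0.0 else 1
        q[s, a] = q[s, a] + eps[2 * d + si] * delta
        if use_pav:
            dv = rr - v[s]
            sj = 0 if dv >= 0.0 else 1
            v[s] = v[s] + eps[2 * d + sj] * dv
    return ll


@njit(cache=True)
def expand_free(x, lr_code, rho_code, has_bias, has_pav):
    """Map a free transformed-scale vector to (eps[4], rho[2], bias, pav).

    lr_code is the number of learning rates (1, 2 or 4); rho_code the number
    of outcome impacts (1 or 2). Learning rates pass through the logistic,
    impacts through exp; bias and Pavlovian weight are identity-mapped.
    """
    eps = np.empty(4)
    rho = np.empty(2)
    i = 0
    if lr_code == 1:
        e = 1.0 / (1.0 + np.exp(-x[0]))
        for j in range(4):
            eps[j] = e
        i = 1
    elif lr_code == 2:
        ep = 1.0 / (1.0 + np.exp(-x[0]))
        en = 1.0 / (1.0 + np.exp(-x[1]))
        eps[0] = ep
        eps[1] = en
        eps[2] = ep
        eps[3] = en
        i = 2
    else:
        for j in range(4):
            eps[j] = 1.0 / (1.0 + np.exp(-x[j]))
        i = 4
    if rho_code == 1:
        r = np.exp(x[i])
        rho[0] = r
        rho[1] = r
        i += 1
    else:
        rho[0] = np.exp(x[i])
        rho[1] = np.exp(x[i + 1])
        i += 2
    b = 0.0
    if has_bias == 1:
        b = x[i]
        i += 1
    p = 0.0
    if has_pav == 1:
        p = x[i]
        i += 1
    return eps, rho, b, p


@njit(cache=True)
def neg_log_posterior(x, lr_code, rho_code, has_bias, has_pav, mu, sigma2,
                      stim, domain, action, outcome):
    """Negative (log-likelihood + log normal prior) on the transformed scale.

    The additive normalization constant of the prior is dropped; it does not
    affect the MAP location or the Laplace curvature.
    """
    pen = 0.0
    for i in range(x.shape[0]):
        d = x[i] - mu[i]
        pen += 0.5 * d * d / sigma2[i]
    eps, rho, b, p = expand_free(x, lr_code, rho_code, has_bias, has_pav)
    return pen - ll_core(eps, rho, b, p, has_pav == 1, stim, domain, action, outcome)


@njit(cache=True)
def neg_log_posterior_grad(x, lr_code, rho_code, has_bias, has_pav, mu, sigma2,
                           stim, domain, action, outcome):
    """Value and exact gradient of :func:`neg_log_posterior`.

    Forward-mode propagation of d(Q)/d(param) and d(V)/d(param) through the
    delta-rule recursion, with the learning-rate selection treated as
    locally constant (the PE-sign switch is non-differentiable only on a
    measure-zero set). Gradients are taken on the expanded natural scale
    (4 eps, 2 rho, bias, pav) and chained to the free transformed vector.
    """
    n = x.shape[0]
    eps, rho, b, p = expand_free(x, lr_code, rho_code, has_bias, has_pav)
    use_pav = has_pav == 1

    # d(ll)/d(expanded natural params), order: eps[0..3], rho[0..1], b, p
    g = np.zeros(8)
    dq = np.zeros((4, 2, 8))
    dv = np.zeros((4, 8))
    dwg = np.empty(8)
    ll = 0.0
    q = np.zeros((4, 2))
    v = np.zeros(4)
    for t in range(stim.shape[0]):
        s = stim[t]
        a = action[t]
        d = domain[t]
        r = outcome[t]
        w_go = q[s, 1] + b
        if use_pav:
            w_go = w_go + p * v[s]
        w_ng = q[s, 0]
        for j in range(8):
            dwg[j] = dq[s, 1, j]
            if use_pav:
                dwg[j] += p * dv[s, j]
        dwg[6] += 1.0      # bias slot
        if use_pav:
            dwg[7] += v[s]  # pavlovian slot
        m = w_go if w_go > w_ng else w_ng
        eg = np.exp(w_go - m)
        en = np.exp(w_ng - m)
        z = eg + en
        p_go = eg / z
        if a == 1:
            ll += w_go - m - np.log(z)
        else:
            ll += w_ng - m - np.log(z)
        # d log p(a) = dw_a - (p_go*dw_go + p_ng*dw_ng)
        coef = (1.0 - p_go) if a == 1 else (-p_go)
        for j in range(8):
            g[j] += coef * (dwg[j] - dq[s, 0, j])
        # updates
        rr = rho[d] * r
        delta = rr - q[s, a]
        si = 0 if delta >= 0.0 else 1
        ei = 2 * d + si
        e = eps[ei]
        for j in range(8):
            drr = r if j == 4 + d else 0.0
            dd = drr - dq[s, a, j]
            dq[s, a, j] = dq[s, a, j] + e * dd
        dq[s, a, ei] += delta
        q[s, a] = q[s, a] + e * delta
        if use_pav:
            dvv = rr - v[s]
            sj = 0 if dvv >= 0.0 else 1
            ej = 2 * d + sj
            ev = eps[ej]
            for j in range(8):
                drr = r if j == 4 + d else 0.0
                ddv = drr - dv[s, j]
                dv[s, j] = dv[s, j] + ev * ddv
            dv[s, ej] += dvv
            v[s] = v[s] + ev * dvv

    # chain expanded-natural gradient to the free transformed vector
    grad = np.empty(n)
    i = 0
    if lr_code == 1:
        grad[0] = (g[0] + g[1] + g[2] + g[3]) * eps[0] * (1.0 - eps[0])
        i = 1
    elif lr_code == 2:
        grad[0] = (g[0] + g[2]) * eps[0] * (1.0 - eps[0])
        grad[1] = (g[1] + g[3]) * eps[1] * (1.0 - eps[1])
        i = 2
    else:
        for j in range(4):
            grad[j] = g[j] * eps[j] * (1.0 - eps[j])
        i = 4
    if rho_code == 1:
        grad[i] = (g[4] + g[5]) * rho[0]
        i += 1
    else:
        grad[i] = g[4] * rho[0]
        grad[i + 1] = g[5] * rho[1]
        i += 2
    if has_bias == 1:
        grad[i] = g[6]
        i += 1
    if has_pav == 1:
        grad[i] = g[7]
        i += 1

    # negative log posterior: prior penalty minus log-likelihood
    pen = 0.0
    for j in range(n):
        dj = x[j] - mu[j]
        pen += 0.5 * dj * dj / sigma2[j]
        grad[j] = -grad[j] + dj / sigma2[j]
    return pen - ll, grad


@njit(cache=True)
def ll_free_batch(X, lr_code, rho_code, has_bias, has_pav, stim, domain, action, outcome):
    """Session log-likelihood for each row of a (k, n_params) free-vector draw."""
    k = X.shape[0]
    out = np.empty(k)
    for j in range(k):
        eps, rho, b, p = expand_free(X[j], lr_code, rho_code, has_bias, has_pav)
        out[j] = ll_core(eps, rho, b, p, has_pav == 1, stim, domain, action, outcome)
    return out
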