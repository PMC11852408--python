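"""Optional numba-compiled log-density kernel.

Numerically identical to ``UnconstrainedPosterior._logp_grad_numpy``
(verified in the test suite); used automatically when numba is
importable. One fit spends ~95% of its time in this function, so the
JIT cuts sampling cost several-fold.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

_LOG_2PI = math.log(2.0 * math.pi)


def _kernel(
    theta,
    P,
    n_multi,
    c,
    kk,
    s_idx,
    s_n,
    s_mean,
    s_ss,
    m_idx,
    m_nbatches,
    m_m,
    m_mean,
    m_ssw,
    A2,
    B2,
    C2,
    const,
):
    grad = np.zeros(theta.shape[0])
    mu_pop = theta[0]
    t = theta[1]
    sigma = math.exp(t)
    logp = const

    logp += -0.5 * mu_pop * mu_pop / A2
    grad[0] = -mu_pop / A2
    logp += -0.5 * sigma * sigma / B2 + t
    grad[1] = 1.0 - sigma * sigma / B2

    ls = np.empty(P)
    s_i = np.empty(P)
    mu_i = np.empty(P)
    g_mu_i = np.empty(P)
    g_ls = np.empty(P)
    for k in range(P):
        u = theta[2 + k]
        v = theta[2 + P + k]
        ls[k] = mu_pop + sigma * v
        s_i[k] = math.exp(ls[k])
        mu_i[k] = c[k] + s_i[k] * kk[k] * u
        # standard-normal v, u-transform Jacobian, product-mean prior
        logp += -0.5 * v * v + ls[k]
        logp += -0.5 * mu_i[k] * mu_i[k] / C2
        g_mu_i[k] = -mu_i[k] / C2
        g_ls[k] = 1.0

    for q in range(s_idx.shape[0]):
        k = s_idx[q]
        inv_s2 = math.exp(-2.0 * ls[k])
        d = s_mean[q] - mu_i[k]
        quad = s_ss[q] + s_n[q] * d * d
        logp += -s_n[q] * ls[k] - 0.5 * quad * inv_s2
        g_mu_i[k] += s_n[q] * d * inv_s2
        g_ls[k] += -s_n[q] + quad * inv_s2

    pos = 0
    for q in range(n_multi):
        k = m_idx[q]
        s2 = s_i[k] * s_i[k]
        l = theta[2 + 2 * P + q]
        if l >= 0.0:
            p = 1.0 / (1.0 + math.exp(-l))
        else:
            e = math.exp(l)
            p = e / (1.0 + e)
        b2 = p * s2
        w2 = s2 - b2
        if not (b2 > 0.0 and w2 > 0.0):  # p underflowed to 0 or 1
            return -np.inf, grad
        g_w2 = 0.0
        g_b2 = 0.0
        for _ in range(m_nbatches[q]):
            m = m_m[pos]
            ybar = m_mean[pos]
            ssw = m_ssw[pos]
            pos += 1
            cc = w2 + m * b2
            d = ybar - mu_i[k]
            logp += (
                -0.5 * (m - 1.0) * math.log(w2)
                - 0.5 * math.log(cc)
                - 0.5 * ssw / w2
                - 0.5 * m * d * d / cc
            )
            g_c = -0.5 / cc + 0.5 * m * d * d / (cc * cc)
            g_w2 += -0.5 * (m - 1.0) / w2 + 0.5 * ssw / (w2 * w2) + g_c
            g_b2 += m * g_c
            g_mu_i[k] += m * d / cc
        g_ls[k] += 2.0 * (w2 * g_w2 + b2 * g_b2)
        logp += math.log(p) + math.log1p(-p)
        grad[2 + 2 * P + q] = (1.0 - 2.0 * p) + s2 * p * (1.0 - p) * (g_b2 - g_w2)

    # chain rule back to (mu, t, u, v): mu_i depends on ls through s_i
    for k in range(P):
        v = theta[2 + P + k]
        h = g_ls[k] + g_mu_i[k] * (mu_i[k] - c[k])
        grad[2 + k] = g_mu_i[k] * s_i[k] * kk[k]
        grad[2 + P + k] = h * sigma - v
        grad[0] += h
        grad[1] += h * sigma * v

    return logp, grad


# numpy error semantics: extreme-underflow points yield inf/nan and are
# rejected as divergences rather than raising mid-trajectory
logp_grad_kernel = (
    njit(cache=False, error_model="numpy")(_kernel) if njit is not None else None
)
logp_grad_reference = _kernel
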