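"""Unconstrained joint log density and gradient for the sampler.

Parameter vector layout (dimension ``2 + 2*n_products + n_multi``)::

    [ mu, log(sigma), u_1..u_P, v_1..v_P, logit(p_1)..logit(p_M) ]

with the non-centered / whitened mapping

* ``ln(sigma_i) = mu + sigma * v_i`` — the lognormal random effect in
  standard-normal coordinates, which removes the population-scale
  funnel at small per-product sample sizes;
* ``mu_i = c_i + sigma_i * k_i * u_i`` with ``c_i`` the product's data
  mean and ``k_i = 1/sqrt(n_batches_i)`` — whitening the product mean
  by its likelihood scale, which removes the ``mu_i``/``sigma_i``
  funnel;
* ``p_i`` is the proportion of product ``i``'s total variance between
  batches (``tau_i^2 = p_i sigma_i^2``), multi-cycle products only.

Latent batch means are integrated out analytically: conditional on
``(mu_i, tau_i, nu_i)`` the cycle values of a batch are jointly normal
with compound-symmetric covariance ``nu^2 I + tau^2 J``. Batch-mean
draws are recovered exactly afterwards from their conjugate normal
conditional (:meth:`UnconstrainedPosterior.sample_batch_means`).

All Jacobian terms are included, so up to the batch-mean
marginalisation this density equals
:func:`varmeta.core_model.log_posterior_unnormalized` plus
``log|d(constrained)/d(unconstrained)|``. A numba-compiled kernel
(:mod:`._kernel`) carries the hot path; `_logp_grad_numpy` is the
reference implementation, kept in exact agreement by the test suite.
"""

from __future__ import annotations

import math

import numpy as np

from ..core_model import (
    MULTI_CYCLE,
    HierarchicalDataset,
    PriorConfig,
)
from . import _kernel

_LOG_2PI = math.log(2.0 * math.pi)


class UnconstrainedPosterior:
    """Fused log-density/gradient of the model on unconstrained space."""

    def __init__(self, data: HierarchicalDataset, prior: PriorConfig) -> None:
        self.prior = prior
        self.product_ids = data.product_ids
        self.n_products = data.n_products
        self.multi_ids = [p for p in self.product_ids if data.mode(p) == MULTI_CYCLE]
        self.n_multi = len(self.multi_ids)
        self.dim = 2 + 2 * self.n_products + self.n_multi

        P = self.n_products
        self._sl_u = slice(2, 2 + P)
        self._sl_v = slice(2 + P, 2 + 2 * P)
        self._sl_l = slice(2 + 2 * P, 2 + 2 * P + self.n_multi)

        # whitening anchors: per-product data mean and 1/sqrt(n_batches)
        self._c = np.array(
            [
                float(np.concatenate(data.batch_values(p)).mean())
                for p in self.product_ids
            ]
        )
        self._k = np.array(
            [1.0 / math.sqrt(len(data.batch_ids(p))) for p in self.product_ids]
        )

        # --- sufficient statistics -------------------------------------
        # single-cycle products: batch-value count, mean and centred SS
        single = [
            (k, p) for k, p in enumerate(self.product_ids) if p not in self.multi_ids
        ]
        self._s_idx = np.array([k for k, _ in single], dtype=np.intp)
        s_stats = [data.single_cycle_values(p) for _, p in single]
        self._s_n = np.array([y.size for y in s_stats], dtype=float)
        self._s_mean = np.array([y.mean() for y in s_stats]) if single else np.empty(0)
        self._s_ss = np.array([((y - y.mean()) ** 2).sum() for y in s_stats]) if single else np.empty(0)

        # multi-cycle products: per-batch cycle count, mean, within-batch
        # SS, flattened with per-product offsets
        self._m_idx = np.array(
            [self.product_ids.index(p) for p in self.multi_ids], dtype=np.intp
        )
        m_m, m_mean, m_ssw, offsets = [], [], [], [0]
        self._m_batches: list[list[np.ndarray]] = []
        for p in self.multi_ids:
            batches = data.batch_values(p)
            self._m_batches.append(batches)
            for y in batches:
                m_m.append(y.size)
                m_mean.append(y.mean())
                m_ssw.append(((y - y.mean()) ** 2).sum())
            offsets.append(offsets[-1] + len(batches))
        self._m_m = np.asarray(m_m, dtype=float)
        self._m_mean = np.asarray(m_mean, dtype=float)
        self._m_ssw = np.asarray(m_ssw, dtype=float)
        self._m_off = np.asarray(offsets[:-1], dtype=np.intp)
        self._m_nbatches = np.diff(np.asarray(offsets, dtype=np.intp))

        # constant part of the log density (likelihood and prior
        # normalisers, random-effect normalisers, whitening constants)
        n_total_obs = float(self._s_n.sum() + self._m_m.sum())
        self._const = (
            -0.5 * n_total_obs * _LOG_2PI
            - 0.5 * _LOG_2PI
            - math.log(prior.mu_prior_sd)
            + math.log(2.0)
            - 0.5 * _LOG_2PI
            - math.log(prior.sigma_prior_sd)
            - P * (0.5 * _LOG_2PI + math.log(prior.product_mean_prior_sd))
            - P * 0.5 * _LOG_2PI  # standard-normal v_i
            + float(np.sum(np.log(self._k)))  # u-transform Jacobian, fixed part
        )

        self._kernel_args = (
            self.n_products,
            self.n_multi,
            self._c,
            self._k,
            self._s_idx,
            self._s_n,
            self._s_mean,
            self._s_ss,
            self._m_idx,
            self._m_nbatches,
            self._m_m,
            self._m_mean,
            self._m_ssw,
            prior.mu_prior_sd**2,
            prior.sigma_prior_sd**2,
            prior.product_mean_prior_sd**2,
            self._const,
        )

    # ------------------------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Constrained view of one unconstrained parameter vector."""
        theta = np.asarray(theta, dtype=float)
        sigma = np.exp(theta[1])
        sigma_i = np.exp(theta[0] + sigma * theta[self._sl_v])
        mu_i = self._c + sigma_i * self._k * theta[self._sl_u]
        out = {
            "mu": theta[0],
            "sigma": sigma,
            "mu_i": mu_i,
            "sigma_i": sigma_i,
        }
        if self.n_multi:
            out["p_i"] = _expit(theta[self._sl_l])
        return out

    def constrain_draws(self, raw: np.ndarray) -> dict[str, np.ndarray]:
        """Vectorised :meth:`unpack` over draws of shape (..., dim)."""
        sigma = np.exp(raw[..., 1])
        v = raw[..., self._sl_v]
        sigma_i = np.exp(raw[..., 0:1] + sigma[..., None] * v)
        mu_i = self._c + sigma_i * self._k * raw[..., self._sl_u]
        out = {
            "mu": raw[..., 0],
            "sigma": sigma,
            "mu_i": mu_i,
            "sigma_i": sigma_i,
        }
        if self.n_multi:
            out["p_i"] = _expit(raw[..., self._sl_l])
        return out

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log density and gradient; JIT-compiled kernel when available."""
        if _kernel.logp_grad_kernel is not None:
            return _kernel.logp_grad_kernel(theta, *self._kernel_args)
        return self._logp_grad_numpy(theta)

    def _logp_grad_numpy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        prior = self.prior
        mu_pop = theta[0]
        t = theta[1]
        sigma = math.exp(t)
        u = theta[self._sl_u]
        v = theta[self._sl_v]

        grad = np.zeros_like(theta)
        logp = self._const

        A, B, C = prior.mu_prior_sd, prior.sigma_prior_sd, prior.product_mean_prior_sd
        logp += -0.5 * mu_pop * mu_pop / (A * A)
        grad[0] += -mu_pop / (A * A)
        logp += -0.5 * sigma * sigma / (B * B) + t  # + log-Jacobian of exp
        grad[1] += 1.0 - sigma * sigma / (B * B)

        # non-centered random effects and whitened product means
        ls = mu_pop + sigma * v
        s_i = np.exp(ls)
        mu_i = self._c + s_i * self._k * u
        logp += -0.5 * float(v @ v)
        # u-transform Jacobian: d mu_i / d u_i = sigma_i * k_i
        logp += float(np.sum(ls))
        logp += -0.5 * float(mu_i @ mu_i) / (C * C)

        g_mu_i = -mu_i / (C * C)  # d logp / d mu_i, to be completed
        g_ls = np.ones(self.n_products)  # Jacobian d(sum ls)/d ls

        # single-cycle likelihood
        if self._s_idx.size:
            idx = self._s_idx
            inv_s2 = np.exp(-2.0 * ls[idx])
            d = self._s_mean - mu_i[idx]
            quad = self._s_ss + self._s_n * d * d
            logp += float(np.sum(-self._s_n * ls[idx] - 0.5 * quad * inv_s2))
            g_mu_i[idx] += self._s_n * d * inv_s2
            g_ls[idx] += -self._s_n + quad * inv_s2

        # multi-cycle likelihood, batch means marginalised
        if self.n_multi:
            idx = self._m_idx
            s2 = np.exp(2.0 * ls[idx])
            l = theta[self._sl_l]
            p = _expit(l)
            b2 = p * s2  # tau^2
            w2 = s2 - b2  # nu^2
            if not (np.all(b2 > 0.0) and np.all(w2 > 0.0)):
                # p underflowed to 0 or 1: off the interior support
                return -math.inf, grad
            w2_b = np.repeat(w2, self._m_nbatches)
            b2_b = np.repeat(b2, self._m_nbatches)
            mu_b = np.repeat(mu_i[idx], self._m_nbatches)
            m = self._m_m
            c = w2_b + m * b2_b
            d = self._m_mean - mu_b
            logp += float(
                np.sum(
                    -0.5 * (m - 1.0) * np.log(w2_b)
                    - 0.5 * np.log(c)
                    - 0.5 * self._m_ssw / w2_b
                    - 0.5 * m * d * d / c
                )
            )
            g_c = -0.5 / c + 0.5 * m * d * d / (c * c)
            g_w2_b = -0.5 * (m - 1.0) / w2_b + 0.5 * self._m_ssw / (w2_b * w2_b) + g_c
            g_w2 = np.add.reduceat(g_w2_b, self._m_off)
            g_b2 = np.add.reduceat(m * g_c, self._m_off)
            g_mu_i[idx] += np.add.reduceat(m * d / c, self._m_off)
            g_ls[idx] += 2.0 * (w2 * g_w2 + b2 * g_b2)
            # uniform prior on p via logit Jacobian: log p + log(1-p)
            logp += float(np.sum(np.log(p) + np.log1p(-p)))
            grad[self._sl_l] += (1.0 - 2.0 * p) + s2 * p * (1.0 - p) * (g_b2 - g_w2)

        # chain rule back to (mu, t, u, v): mu_i depends on ls through s_i
        h = g_ls + g_mu_i * (mu_i - self._c)  # total d logp / d ls
        grad[self._sl_u] += g_mu_i * s_i * self._k
        grad[self._sl_v] += h * sigma - v
        grad[0] += float(np.sum(h))
        grad[1] += float(np.sum(h * sigma * v))
        return float(logp), grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # ------------------------------------------------------------------

    def initial_point(self, rng: np.random.Generator, jitter: float = 1.0) -> np.ndarray:
        """Data-informed start with per-chain jitter.

        In whitened coordinates the bulk of the posterior sits near the
        origin, so the start is the anchor point plus noise.
        """
        theta = np.zeros(self.dim)
        ls0 = np.zeros(self.n_products)
        for k, pid in enumerate(self.product_ids):
            if pid in self.multi_ids:
                vals = np.concatenate(self._m_batches[self.multi_ids.index(pid)])
            else:
                i = int(np.searchsorted(self._s_idx, k))
                n = self._s_n[i]
                sd = math.sqrt(self._s_ss[i] / (n - 1)) if n > 1 else 1.0
                ls0[k] = math.log(max(sd, 1e-3))
                continue
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 1.0
            ls0[k] = math.log(max(sd, 1e-3))
        theta[0] = float(np.mean(ls0))
        sigma0 = max(float(np.std(ls0)), 0.1)
        theta[1] = math.log(sigma0)
        theta[self._sl_v] = (ls0 - theta[0]) / sigma0
        theta += jitter * rng.normal(scale=0.2, size=self.dim)
        return theta

    def sample_batch_means(
        self, theta: np.ndarray, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        """Exact conjugate draw of the latent batch means given ``theta``.

        For batch ``j`` of product ``i``:
        ``mu_ij | rest ~ N((mu_i/tau^2 + m ybar/nu^2) / k, 1/k)`` with
        ``k = 1/tau^2 + m/nu^2``.
        """
        if not self.n_multi:
            return {}
        pars = self.unpack(theta)
        s2 = pars["sigma_i"][self._m_idx] ** 2
        tau2 = pars["p_i"] * s2
        nu2 = s2 - tau2
        out: dict[str, np.ndarray] = {}
        pos = 0
        for q, pid in enumerate(self.multi_ids):
            nb = int(self._m_nbatches[q])
            m = self._m_m[pos : pos + nb]
            ybar = self._m_mean[pos : pos + nb]
            pos += nb
            prec = 1.0 / tau2[q] + m / nu2[q]
            mean = (pars["mu_i"][self._m_idx[q]] / tau2[q] + m * ybar / nu2[q]) / prec
            out[pid] = mean + rng.standard_normal(nb) / np.sqrt(prec)
        return out


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
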