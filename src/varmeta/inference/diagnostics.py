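"""MCMC convergence diagnostics: split-R-hat and effective sample size.

Implemented here rather than delegated so the formulas stay testable
against hand-written oracles; values agree with the standard
split-chain definitions used by modern samplers.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["rhat", "effective_sample_size"]


def _as_chain_matrix(chain_values) -> np.ndarray:
    x = np.asarray(chain_values, dtype=float)
    if x.ndim == 1:
        # single sequence: treat its two halves as chains
        n = x.size // 2
        x = np.stack([x[:n], x[n : 2 * n]])
    if x.ndim != 2:
        raise ValueError("chain_values must be 1-D or (n_chains, n_draws)")
    return x


def _split(x: np.ndarray) -> np.ndarray:
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)


def rhat(chain_values) -> float:
    """Split-R-hat: potential scale reduction over halved chains.

    Returns NaN (with a warning) when every half-chain is constant.
    """
    x = np.asarray(chain_values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains of draws")
    if x.shape[1] < 4:
        raise ValueError("rhat requires at least 4 draws per chain")
    halves = _split(x)
    m, n = halves.shape
    within = np.var(halves, axis=1, ddof=1)
    w = float(np.mean(within))
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", UserWarning)
        return float("nan")
    b_over_n = float(np.var(np.mean(halves, axis=1), ddof=1))  # B/n
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance of each row via FFT, all lags."""
    m, n = x.shape
    centred = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centred, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def effective_sample_size(chain_values) -> float:
    """Autocorrelation-adjusted effective number of draws.

    Uses split chains, chain-averaged autocovariances, and Geyer's
    initial monotone positive sequence to truncate the autocorrelation
    sum. Accepts a single 1-D sequence (treated as one chain and split
    in half) or an (n_chains, n_draws) array.
    """
    x = _as_chain_matrix(chain_values)
    if x.shape[1] < 4:
        raise ValueError("effective_sample_size requires at least 4 draws per chain")
    halves = _split(x)
    m, n = halves.shape
    chain_var = np.var(halves, axis=1, ddof=1)
    if np.all(chain_var == 0.0):
        warnings.warn("constant chains; ESS undefined", UserWarning)
        return float("nan")
    w = float(np.mean(chain_var))
    acov = _autocovariance(halves)
    mean_acov = acov.mean(axis=0)
    if m > 1:
        b_over_n = float(np.var(np.mean(halves, axis=1), ddof=1))
    else:
        b_over_n = 0.0
    var_plus = (n - 1) / n * w + b_over_n
    if var_plus <= 0.0:
        warnings.warn("non-positive variance estimate; ESS undefined", UserWarning)
        return float("nan")

    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer initial monotone positive sequence: sum pairs P_k = rho_2k + rho_2k+1
    # while positive and non-increasing; tau = -1 + 2 * sum P_k.
    prev_pair = np.inf
    pair_sum = 0.0
    k = 0
    while 2 * k + 1 < n:
        pair = rho[2 * k] + rho[2 * k + 1]
        if pair <= 0.0:
            break
        pair = min(pair, prev_pair)
        pair_sum += pair
        prev_pair = pair
        k += 1
    tau = max(-1.0 + 2.0 * pair_sum, 1.0)
    return float(m * n / tau)
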