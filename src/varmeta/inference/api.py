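"""Posterior sampling, draw containers, and the predictive distribution.

`sample_posterior` targets the exact density assembled in
:mod:`varmeta.core_model` (on unconstrained space, with latent batch
means marginalised analytically and recovered by conjugate draws) using
the bundled no-U-turn sampler. Diagnostics are computed with this
package's own split-R-hat and ESS implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core_model import HierarchicalDataset, PriorConfig
from ._density import UnconstrainedPosterior
from ._nuts import nuts_sample
from .diagnostics import effective_sample_size, rhat

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PredictiveDraws",
    "ConvergenceWarning",
    "sample_posterior",
    "posterior_predictive_S",
    "credible_interval",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds its threshold."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults follow the reference analysis.

    ``n_iterations`` counts draws per chain including warmup; retained
    draws total ``n_chains * (n_iterations - n_warmup) / thin`` (4000
    with the defaults). ``init_step_size`` seeds step-size adaptation,
    which remains active (target acceptance 0.95).
    """

    n_chains: int = 2
    n_iterations: int = 5000
    n_warmup: int = 1000
    thin: int = 2
    target_accept: float = 0.95
    init_step_size: float = 0.05
    max_tree_depth: int = 15
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < self.n_warmup < self.n_iterations:
            raise ValueError("need 0 < n_warmup < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")

    @property
    def n_retained(self) -> int:
        return self.n_chains * ((self.n_iterations - self.n_warmup) // self.thin)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain structure and diagnostics.

    ``draws`` has shape ``(n_chains, n_draws_per_chain, n_params)``;
    ``names`` labels the last axis. ``diagnostics`` maps each parameter
    to ``{"rhat": ..., "ess": ...}``.
    """

    names: list[str]
    draws: np.ndarray
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    n_divergent: int = 0
    n_max_treedepth: int = 0
    config: McmcConfig | None = None

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, draws, params)")
        self._col = {name: k for k, name in enumerate(self.names)}

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.get_chains(name).reshape(-1)

    def get_chains(self, name: str) -> np.ndarray:
        if name not in self._col:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[:, :, self._col[name]]

    def mean(self, name: str) -> float:
        return float(np.mean(self.get(name)))

    @property
    def converged(self) -> bool:
        threshold = self.config.rhat_threshold if self.config else 1.05
        values = [d["rhat"] for d in self.diagnostics.values()]
        return all(not math.isnan(v) and v <= threshold for v in values)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: (chain, iteration, parameter, value)."""
        n_chains, n_draws, n_params = self.draws.shape
        chain = np.repeat(np.arange(n_chains), n_draws * n_params)
        iteration = np.tile(np.repeat(np.arange(n_draws), n_params), n_chains)
        parameter = np.tile(np.asarray(self.names, dtype=object), n_chains * n_draws)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.draws.reshape(-1),
            }
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "PosteriorDraws":
        pivot = frame.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value",
            sort=False,
        )
        names = list(pivot.columns)
        n_chains = frame["chain"].nunique()
        arr = pivot.to_numpy().reshape(n_chains, -1, len(names))
        return cls(names=names, draws=arr)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            x = self.get(name)
            diag = self.diagnostics.get(name, {})
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "q2.5": float(np.quantile(x, 0.025)),
                    "q97.5": float(np.quantile(x, 0.975)),
                    "rhat": diag.get("rhat", float("nan")),
                    "ess": diag.get("ess", float("nan")),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PredictiveDraws:
    """Samples of a future product's total SD."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if np.any(self.samples <= 0):
            raise ValueError("predictive SD samples must be positive")

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.samples, alpha)),
            float(np.quantile(self.samples, 1.0 - alpha)),
        )

    @property
    def variance_samples(self) -> np.ndarray:
        """The same draws on the variance scale, S^2."""
        return self.samples**2


def sample_posterior(
    data: HierarchicalDataset,
    prior: PriorConfig | None = None,
    cfg: McmcConfig | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of all model parameters with NUTS.

    Warmup is discarded and thinning applied per chain. Latent batch
    means of multi-cycle products are marginalised during sampling and
    re-drawn exactly from their conjugate conditional for every retained
    draw, so the returned draws cover ``mu``, ``sigma``, all ``mu_i``,
    ``sigma_i`` and, where applicable, ``p_i``, ``tau_i``, ``nu_i`` and
    ``mu_ij``. A warning (never a silent pass) is emitted when any
    split-R-hat exceeds ``cfg.rhat_threshold``.
    """
    prior = prior or PriorConfig()
    cfg = cfg or McmcConfig()
    model = UnconstrainedPosterior(data, prior)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains + 1)
    aux_rng = np.random.default_rng(seeds[-1])

    per_chain = (cfg.n_iterations - cfg.n_warmup) // cfg.thin
    raw = np.empty((cfg.n_chains, per_chain, model.dim))
    n_div = 0
    n_deep = 0
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        init = model.initial_point(rng)
        res = nuts_sample(
            model.logp_grad,
            init,
            cfg.n_iterations,
            cfg.n_warmup,
            rng,
            target_accept=cfg.target_accept,
            init_step_size=cfg.init_step_size,
            max_tree_depth=cfg.max_tree_depth,
        )
        raw[c] = res.draws[cfg.thin - 1 :: cfg.thin][:per_chain]
        n_div += res.n_divergent
        n_deep += res.n_max_treedepth

    names, columns = _constrained_columns(model, raw, aux_rng)
    draws = np.stack(columns, axis=2)
    post = PosteriorDraws(
        names=names,
        draws=draws,
        n_divergent=n_div,
        n_max_treedepth=n_deep,
        config=cfg,
    )
    for name in names:
        chains = post.get_chains(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            post.diagnostics[name] = {
                "rhat": rhat(chains) if cfg.n_chains >= 2 else float("nan"),
                "ess": effective_sample_size(chains),
            }
    bad = {
        name: diag["rhat"]
        for name, diag in post.diagnostics.items()
        if math.isnan(diag["rhat"]) or diag["rhat"] > cfg.rhat_threshold
    }
    if bad and cfg.n_chains >= 2:
        worst = max(bad, key=lambda k: bad[k])
        warnings.warn(
            f"possible non-convergence: {len(bad)} parameter(s) with "
            f"R-hat > {cfg.rhat_threshold} (worst {worst}: {bad[worst]:.3f})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return post


def _constrained_columns(
    model: UnconstrainedPosterior, raw: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], list[np.ndarray]]:
    """Map unconstrained draws to named constrained parameter columns."""
    pars = model.constrain_draws(raw)
    sigma_i = pars["sigma_i"]
    names = ["mu", "sigma"]
    cols = [pars["mu"], pars["sigma"]]
    for k, pid in enumerate(model.product_ids):
        names.append(f"mu_i[{pid}]")
        cols.append(pars["mu_i"][:, :, k])
    for k, pid in enumerate(model.product_ids):
        names.append(f"sigma_i[{pid}]")
        cols.append(sigma_i[:, :, k])
    if model.n_multi:
        p = pars["p_i"]
        for q, pid in enumerate(model.multi_ids):
            k = model._m_idx[q]
            names.append(f"p_i[{pid}]")
            cols.append(p[:, :, q])
            names.append(f"tau_i[{pid}]")
            cols.append(np.sqrt(p[:, :, q]) * sigma_i[:, :, k])
            names.append(f"nu_i[{pid}]")
            cols.append(np.sqrt(1.0 - p[:, :, q]) * sigma_i[:, :, k])
        # conjugate batch-mean draws, vectorised over all retained draws:
        # mu_ij | rest ~ N((mu_i/tau^2 + m*ybar/nu^2)/k, 1/k), k = 1/tau^2 + m/nu^2
        pos = 0
        for q, pid in enumerate(model.multi_ids):
            k = model._m_idx[q]
            nb = int(model._m_nbatches[q])
            m = model._m_m[pos : pos + nb]
            ybar = model._m_mean[pos : pos + nb]
            pos += nb
            tau2 = p[:, :, q, None] * sigma_i[:, :, k, None] ** 2
            nu2 = (1.0 - p[:, :, q, None]) * sigma_i[:, :, k, None] ** 2
            prec = 1.0 / tau2 + m / nu2
            mean = (pars["mu_i"][:, :, k, None] / tau2 + m * ybar / nu2) / prec
            bm = mean + rng.standard_normal(mean.shape) / np.sqrt(prec)
            for j in range(nb):
                names.append(f"mu_ij[{pid},{j + 1}]")
                cols.append(bm[:, :, j])
    return names, cols


def posterior_predictive_S(
    post: PosteriorDraws,
    rng: np.random.Generator | None = None,
    n_per_draw: int = 1,
) -> PredictiveDraws:
    """Predictive distribution of a future product's total SD.

    One ``S = exp(mu_d + sigma_d * z)`` per retained posterior draw
    (``n_per_draw`` controls extra z-draws per posterior draw), which
    marginalises the population model over the posterior of (mu, sigma).
    """
    if rng is None:
        rng = np.random.default_rng()
    mu = np.repeat(post.get("mu"), n_per_draw)
    sigma = np.repeat(post.get("sigma"), n_per_draw)
    z = rng.standard_normal(mu.size)
    return PredictiveDraws(np.exp(mu + sigma * z))


def credible_interval(
    post: PosteriorDraws, param: str, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed quantile interval of one parameter's retained draws."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = post.get(param)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(x, alpha)), float(np.quantile(x, 1.0 - alpha))
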