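"""Domain types and joint log density of the hierarchical random-variance model.

The model pools quality-attribute measurements across products. Each
product's total standard deviation ``sigma_i`` is a random effect drawn
from a lognormal population, ``ln(sigma_i) ~ N(mu, sigma)``, and the
population parameters ``(mu, sigma)`` are the quantities of interest.

Two observation layers are supported and may be mixed in one dataset:

* single-cycle products: one measurement per batch,
  ``y_ij ~ N(mu_i, sigma_i)``;
* multi-cycle products: several cycle measurements per batch with a
  latent batch mean, ``mu_ij ~ N(mu_i, tau_i)`` and
  ``y_ijk ~ N(mu_ij, nu_i)``, where ``sigma_i^2 = tau_i^2 + nu_i^2``.

All densities are natural-log. Everything here is pure computation; the
MCMC machinery lives in :mod:`varmeta.inference`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Measurement",
    "HierarchicalDataset",
    "PopulationParams",
    "ProductEffects",
    "BatchEffects",
    "PriorConfig",
    "SINGLE_CYCLE",
    "MULTI_CYCLE",
    "log_prior",
    "loglik_single_cycle",
    "loglik_multi_cycle",
    "loglik_multi_cycle_marginal",
    "log_random_effect",
    "log_posterior_unnormalized",
]

SINGLE_CYCLE = "single_cycle"
MULTI_CYCLE = "multi_cycle"

_LOG_2PI = math.log(2.0 * math.pi)

#: relative tolerance for the variance decomposition sigma_i^2 = tau_i^2 + nu_i^2
VARIANCE_SPLIT_RTOL = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Measurement:
    """A single quality-attribute measurement.

    ``cycle_id`` is ``None`` for single-cycle rows (one measurement per
    batch). The triple ``(product_id, batch_id, cycle_id)`` must be
    unique within a dataset.
    """

    product_id: str
    batch_id: str
    cycle_id: str | None
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(
                f"measurement value must be finite, got {self.value!r} "
                f"for ({self.product_id}, {self.batch_id}, {self.cycle_id})"
            )

    @property
    def key(self) -> tuple[str, str, str | None]:
        return (self.product_id, self.batch_id, self.cycle_id)


class HierarchicalDataset:
    """Measurements organised product -> batch -> cycle.

    Parameters
    ----------
    measurements
        Iterable of :class:`Measurement`. Order is irrelevant; products
        and batches keep first-appearance order.
    modes
        Optional explicit per-product mode map (``"single_cycle"`` or
        ``"multi_cycle"``). When given it is cross-checked against the
        data: a product is multi-cycle iff at least one of its batches
        carries two or more cycle values.
    """

    def __init__(
        self,
        measurements: Iterable[Measurement],
        modes: Mapping[str, str] | None = None,
    ) -> None:
        measurements = list(measurements)
        if not measurements:
            raise ValueError("dataset must contain at least one measurement")

        seen: set[tuple[str, str, str | None]] = set()
        index: dict[str, dict[str, list[float]]] = {}
        for m in measurements:
            if m.key in seen:
                raise ValueError(f"duplicate measurement key {m.key}")
            seen.add(m.key)
            index.setdefault(m.product_id, {}).setdefault(m.batch_id, []).append(
                float(m.value)
            )

        inferred = {
            pid: (
                MULTI_CYCLE
                if any(len(vals) >= 2 for vals in batches.values())
                else SINGLE_CYCLE
            )
            for pid, batches in index.items()
        }
        if modes is not None:
            for pid, mode in modes.items():
                if pid not in inferred:
                    raise ValueError(f"mode given for unknown product {pid!r}")
                if mode not in (SINGLE_CYCLE, MULTI_CYCLE):
                    raise ValueError(f"invalid mode {mode!r} for product {pid!r}")
                if mode != inferred[pid]:
                    raise ValueError(
                        f"declared mode {mode!r} for product {pid!r} disagrees "
                        f"with the data (inferred {inferred[pid]!r})"
                    )

        self._measurements = measurements
        self._index = index
        self._modes = inferred

        for pid, batches in index.items():
            n_batches = len(batches)
            if inferred[pid] == SINGLE_CYCLE and n_batches == 1:
                warnings.warn(
                    f"product {pid!r} has a single observation; its SD is "
                    "informed almost entirely by the population distribution",
                    UserWarning,
                    stacklevel=2,
                )

    # -- accessors ---------------------------------------------------------

    @property
    def measurements(self) -> list[Measurement]:
        return list(self._measurements)

    @property
    def product_ids(self) -> list[str]:
        return list(self._index)

    @property
    def n_products(self) -> int:
        return len(self._index)

    def mode(self, product_id: str) -> str:
        return self._modes[product_id]

    @property
    def modes(self) -> dict[str, str]:
        return dict(self._modes)

    def batch_ids(self, product_id: str) -> list[str]:
        return list(self._index[product_id])

    def batch_values(self, product_id: str) -> list[np.ndarray]:
        """Per-batch cycle values, in batch order."""
        return [
            np.asarray(vals, dtype=float)
            for vals in self._index[product_id].values()
        ]

    def single_cycle_values(self, product_id: str) -> np.ndarray:
        """Flat vector of the one-per-batch values of a single-cycle product."""
        if self._modes[product_id] != SINGLE_CYCLE:
            raise ValueError(f"product {product_id!r} is not single-cycle")
        return np.array(
            [vals[0] for vals in self._index[product_id].values()], dtype=float
        )

    def __len__(self) -> int:
        return len(self._measurements)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_multi = sum(1 for m in self._modes.values() if m == MULTI_CYCLE)
        return (
            f"HierarchicalDataset(n_products={self.n_products}, "
            f"n_measurements={len(self)}, n_multi_cycle={n_multi})"
        )


@dataclass(frozen=True)
class PopulationParams:
    """Location and scale of the lognormal population of product SDs.

    ``sigma = 0`` (a point-mass population) is accepted here so the
    simulator can express degenerate designs; the density operations
    require ``sigma > 0``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ValueError(f"population sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ProductEffects:
    """Per-product fixed effects.

    ``tau_i`` (between-batch SD) and ``nu_i`` (within-batch SD) are only
    present for multi-cycle products and must satisfy
    ``sigma_i^2 = tau_i^2 + nu_i^2``.
    """

    mu_i: float
    sigma_i: float
    tau_i: float | None = None
    nu_i: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma_i > 0:
            raise ValueError(f"sigma_i must be > 0, got {self.sigma_i}")
        if (self.tau_i is None) != (self.nu_i is None):
            raise ValueError("tau_i and nu_i must be given together")
        if self.tau_i is not None:
            if self.tau_i < 0 or self.nu_i < 0:
                raise ValueError("tau_i and nu_i must be >= 0")
            total = self.tau_i**2 + self.nu_i**2
            if abs(total - self.sigma_i**2) > VARIANCE_SPLIT_RTOL * self.sigma_i**2:
                raise ValueError(
                    f"sigma_i^2 = tau_i^2 + nu_i^2 violated: "
                    f"{self.sigma_i**2} != {total}"
                )

    @property
    def is_multi_cycle(self) -> bool:
        return self.tau_i is not None

    @property
    def p_i(self) -> float | None:
        """Proportion of total variance attributed to between-batch spread."""
        if self.tau_i is None:
            return None
        return self.tau_i**2 / self.sigma_i**2

    @classmethod
    def from_proportion(
        cls, mu_i: float, sigma_i: float, p_i: float
    ) -> "ProductEffects":
        """Build multi-cycle effects from the variance proportion ``p_i``."""
        if not 0.0 <= p_i <= 1.0:
            raise ValueError(f"p_i must lie in [0, 1], got {p_i}")
        tau = math.sqrt(p_i) * sigma_i
        nu = math.sqrt(1.0 - p_i) * sigma_i
        return cls(mu_i=mu_i, sigma_i=sigma_i, tau_i=tau, nu_i=nu)


@dataclass(frozen=True)
class BatchEffects:
    """Latent batch means ``mu_ij`` of one multi-cycle product, in batch order."""

    mu_ij: tuple[float, ...]

    def __init__(self, mu_ij: Sequence[float]) -> None:
        object.__setattr__(self, "mu_ij", tuple(float(v) for v in mu_ij))


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors.

    ``mu ~ N(0, mu_prior_sd)``; ``sigma ~ half-N(0, sigma_prior_sd)``;
    ``mu_i ~ N(0, product_mean_prior_sd)``; and for multi-cycle products
    the variance proportion ``p_i ~ Uniform(0, 1)``.
    """

    mu_prior_sd: float = 1.0
    sigma_prior_sd: float = 1.0
    product_mean_prior_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("mu_prior_sd", "sigma_prior_sd", "product_mean_prior_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


# ---------------------------------------------------------------------------
# Log-density building blocks
# ---------------------------------------------------------------------------


def _log_normal_pdf(x: float, loc: float, sd: float) -> float:
    z = (x - loc) / sd
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z


def log_prior(
    pop: PopulationParams,
    effects: Sequence[ProductEffects],
    prior: PriorConfig,
) -> float:
    """Joint log prior of the population parameters and product effects.

    ``log N(mu | 0, mu_prior_sd) + log half-N(sigma | 0, sigma_prior_sd)
    + sum_i log N(mu_i | 0, product_mean_prior_sd)
    + sum_{i multi} log U(p_i | 0, 1)``.

    The uniform terms contribute 0 but their support is checked.
    """
    if not pop.sigma > 0:
        raise ValueError(f"population sigma must be > 0, got {pop.sigma}")
    total = _log_normal_pdf(pop.mu, 0.0, prior.mu_prior_sd)
    # half-normal: 2 * phi(x / sd) / sd on x > 0
    total += math.log(2.0) + _log_normal_pdf(pop.sigma, 0.0, prior.sigma_prior_sd)
    for eff in effects:
        total += _log_normal_pdf(eff.mu_i, 0.0, prior.product_mean_prior_sd)
        p = eff.p_i
        if p is not None and not 0.0 <= p <= 1.0:  # pragma: no cover - guarded
            raise ValueError(f"p_i out of [0, 1]: {p}")
    return total


def loglik_single_cycle(values: np.ndarray | Sequence[float], eff: ProductEffects) -> float:
    """``sum_j log N(y_ij | mu_i, sigma_i)`` for a single-cycle product."""
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("single-cycle product must have at least one batch value")
    if eff.is_multi_cycle:
        raise ValueError("multi-cycle effects supplied for a single-cycle product")
    z = (y - eff.mu_i) / eff.sigma_i
    return float(
        -0.5 * y.size * _LOG_2PI - y.size * math.log(eff.sigma_i) - 0.5 * np.sum(z * z)
    )


def loglik_multi_cycle(
    batch_values: Sequence[np.ndarray | Sequence[float]],
    eff: ProductEffects,
    batch_means: BatchEffects,
) -> float:
    """Hierarchical log likelihood of one multi-cycle product.

    ``sum_j log N(mu_ij | mu_i, tau_i) + sum_jk log N(y_ijk | mu_ij, nu_i)``.
    """
    if not eff.is_multi_cycle:
        raise ValueError("single-cycle effects supplied for a multi-cycle product")
    if not (eff.tau_i > 0 and eff.nu_i > 0):
        raise ValueError(
            f"tau_i and nu_i must be > 0 inside the sampled region, "
            f"got tau_i={eff.tau_i}, nu_i={eff.nu_i}"
        )
    if len(batch_values) == 0:
        raise ValueError("multi-cycle product must have at least one batch")
    if len(batch_means.mu_ij) != len(batch_values):
        raise ValueError(
            f"got {len(batch_means.mu_ij)} batch means for "
            f"{len(batch_values)} batches"
        )
    total = 0.0
    for m_ij, vals in zip(batch_means.mu_ij, batch_values):
        total += _log_normal_pdf(m_ij, eff.mu_i, eff.tau_i)
        y = np.asarray(vals, dtype=float)
        if y.size == 0:
            raise ValueError("every batch must contain at least one cycle value")
        z = (y - m_ij) / eff.nu_i
        total += -0.5 * y.size * _LOG_2PI - y.size * math.log(eff.nu_i) - 0.5 * float(
            np.sum(z * z)
        )
    return total


def loglik_multi_cycle_marginal(
    batch_values: Sequence[np.ndarray | Sequence[float]],
    eff: ProductEffects,
) -> float:
    """Multi-cycle log likelihood with the batch means integrated out.

    Per batch the cycle values are jointly normal with mean ``mu_i`` and
    compound-symmetric covariance ``nu_i^2 I + tau_i^2 J``; this is the
    exact marginal of :func:`loglik_multi_cycle` over
    ``mu_ij ~ N(mu_i, tau_i)``.
    """
    if not eff.is_multi_cycle:
        raise ValueError("single-cycle effects supplied for a multi-cycle product")
    if not (eff.tau_i > 0 and eff.nu_i > 0):
        raise ValueError("tau_i and nu_i must be > 0")
    tau2 = eff.tau_i**2
    nu2 = eff.nu_i**2
    total = 0.0
    for vals in batch_values:
        y = np.asarray(vals, dtype=float)
        m = y.size
        if m == 0:
            raise ValueError("every batch must contain at least one cycle value")
        ybar = float(np.mean(y))
        ss_within = float(np.sum((y - ybar) ** 2))
        c = nu2 + m * tau2
        total += (
            -0.5 * m * _LOG_2PI
            - 0.5 * (m - 1) * math.log(nu2)
            - 0.5 * math.log(c)
            - 0.5 * ss_within / nu2
            - 0.5 * m * (ybar - eff.mu_i) ** 2 / c
        )
    return total


def log_random_effect(eff: ProductEffects, pop: PopulationParams) -> float:
    """Lognormal log density of the product SD with respect to ``sigma_i``.

    ``log N(ln sigma_i | mu, sigma) - ln sigma_i`` — the Jacobian of the
    log transform is included, so ``exp(.)`` integrates to 1 over
    ``sigma_i in (0, inf)``.
    """
    if not eff.sigma_i > 0:
        raise ValueError(f"sigma_i must be > 0, got {eff.sigma_i}")
    if not pop.sigma > 0:
        raise ValueError(f"population sigma must be > 0, got {pop.sigma}")
    return _log_normal_pdf(math.log(eff.sigma_i), pop.mu, pop.sigma) - math.log(
        eff.sigma_i
    )


def log_posterior_unnormalized(
    data: HierarchicalDataset,
    pop: PopulationParams,
    effects: Mapping[str, ProductEffects],
    batch_means: Mapping[str, BatchEffects],
    prior: PriorConfig,
) -> float:
    """Unnormalised joint log posterior: prior + random effects + likelihood.

    ``effects`` maps product id to :class:`ProductEffects`;
    ``batch_means`` maps every multi-cycle product id to its
    :class:`BatchEffects`. The result decomposes exactly as
    ``log_prior + sum_i log_random_effect + sum_i loglik_i``.
    """
    eff_list = []
    for pid in data.product_ids:
        if pid not in effects:
            raise ValueError(f"missing effects for product {pid!r}")
        eff = effects[pid]
        mode = data.mode(pid)
        if (mode == MULTI_CYCLE) != eff.is_multi_cycle:
            raise ValueError(
                f"effects for product {pid!r} do not match its mode {mode!r}"
            )
        if mode == MULTI_CYCLE and pid not in batch_means:
            raise ValueError(f"missing batch means for multi-cycle product {pid!r}")
        eff_list.append(eff)

    total = log_prior(pop, eff_list, prior)
    for pid, eff in zip(data.product_ids, eff_list):
        total += log_random_effect(eff, pop)
        if data.mode(pid) == SINGLE_CYCLE:
            total += loglik_single_cycle(data.single_cycle_values(pid), eff)
        else:
            total += loglik_multi_cycle(data.batch_values(pid), eff, batch_means[pid])
    return total
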