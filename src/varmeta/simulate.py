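"""Synthetic data generation for the simulation study.

Single-cycle path: product SDs ``sigma_i = exp(mu + sigma * z_i)`` are
drawn from the lognormal population, then one value per batch
``y_ij ~ N(mu_i, sigma_i)``. Multi-cycle path: each ``sigma_i`` is split
into between-batch and within-batch components at a fixed ``tau/nu``
ratio, batch means ``mu_ij ~ N(mu_i, tau_i)`` are drawn and cycle values
``y_ijk ~ N(mu_ij, nu_i)`` around them.

Replicate streams are spawned from a root seed via
``numpy.random.SeedSequence(seed, spawn_key=(rep_index,))`` so scenario
cells are reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    HierarchicalDataset,
    Measurement,
    PopulationParams,
)

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "draw_product_sds",
    "split_total_sd",
    "simulate_dataset",
    "replicate_rng",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation grid.

    ``n_cycles == 1`` selects the single-cycle generation path, in which
    case ``tau_nu_ratio`` must be ``None``; ``n_cycles > 1`` requires it.
    """

    n_products: int
    n_batches: int
    pop: PopulationParams
    n_cycles: int = 1
    tau_nu_ratio: float | None = None
    product_means: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.is_multi_cycle:
            if self.tau_nu_ratio is None or not self.tau_nu_ratio > 0:
                raise ValueError(
                    "multi-cycle designs (n_cycles > 1) require tau_nu_ratio > 0"
                )
        elif self.tau_nu_ratio is not None:
            raise ValueError("tau_nu_ratio is only meaningful when n_cycles > 1")
        if self.product_means is not None:
            if len(self.product_means) != self.n_products:
                raise ValueError(
                    f"product_means has length {len(self.product_means)}, "
                    f"expected n_products={self.n_products}"
                )
            object.__setattr__(
                self, "product_means", tuple(float(v) for v in self.product_means)
            )

    @property
    def is_multi_cycle(self) -> bool:
        return self.n_cycles > 1

    def means(self) -> np.ndarray:
        if self.product_means is None:
            return np.zeros(self.n_products)
        return np.asarray(self.product_means, dtype=float)


@dataclass(frozen=True)
class SimulationTruth:
    """Latent truths behind one simulated dataset, for recovery testing."""

    pop: PopulationParams
    mu_i: np.ndarray
    sigma_i: np.ndarray
    tau_i: np.ndarray | None = None
    nu_i: np.ndarray | None = None
    mu_ij: np.ndarray | None = None  # shape (n_products, n_batches)


def replicate_rng(seed: int, rep_index: int = 0) -> np.random.Generator:
    """Independent child stream for replicate ``rep_index`` of root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep_index,)))


def draw_product_sds(
    pop: PopulationParams | None = None,
    n_products: int = 1,
    rng: np.random.Generator | None = None,
    *,
    mu: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Draw ``sigma_i = exp(mu + sigma * z_i)``, ``z_i`` iid standard normal.

    Accepts either a :class:`PopulationParams` or explicit ``mu``/``sigma``
    (``sigma = 0`` degenerates to all ``sigma_i = exp(mu)``).
    """
    if pop is not None:
        mu, sigma = pop.mu, pop.sigma
    if mu is None or sigma is None:
        raise ValueError("either pop or both mu and sigma must be given")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_products < 1:
        raise ValueError("n_products must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    z = rng.standard_normal(n_products)
    return np.exp(mu + sigma * z)


def split_total_sd(sigma_i: float, ratio: float) -> tuple[float, float]:
    """Split a total SD into ``(tau_i, nu_i)`` with ``tau_i / nu_i = ratio``.

    ``nu_i = sigma_i / sqrt(1 + ratio^2)`` and ``tau_i = ratio * nu_i``,
    so ``tau_i^2 + nu_i^2 = sigma_i^2`` exactly.
    """
    if not sigma_i > 0:
        raise ValueError(f"sigma_i must be > 0, got {sigma_i}")
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    nu = sigma_i / math.sqrt(1.0 + ratio * ratio)
    return ratio * nu, nu


def _labels(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{k + 1:0{width}d}" for k in range(n)]


def simulate_dataset(
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[HierarchicalDataset, SimulationTruth]:
    """Generate one dataset plus all latent truths.

    Uses ``design.seed`` when no generator is supplied; an identical seed
    and design yields a bit-identical dataset.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)

    n_p, n_b, n_c = design.n_products, design.n_batches, design.n_cycles
    mu_i = design.means()
    sigma_i = draw_product_sds(design.pop, n_p, rng)

    products = _labels("P", n_p)
    batches = _labels("B", n_b)
    measurements: list[Measurement] = []

    if not design.is_multi_cycle:
        for i, pid in enumerate(products):
            y = rng.normal(mu_i[i], sigma_i[i], size=n_b)
            measurements.extend(
                Measurement(pid, batches[j], None, y[j]) for j in range(n_b)
            )
        truth = SimulationTruth(pop=design.pop, mu_i=mu_i, sigma_i=sigma_i)
        return HierarchicalDataset(measurements), truth

    cycles = _labels("C", n_c)
    tau_i = np.empty(n_p)
    nu_i = np.empty(n_p)
    for i in range(n_p):
        tau_i[i], nu_i[i] = split_total_sd(float(sigma_i[i]), design.tau_nu_ratio)
    mu_ij = rng.normal(mu_i[:, None], tau_i[:, None], size=(n_p, n_b))
    for i, pid in enumerate(products):
        for j, bid in enumerate(batches):
            y = rng.normal(mu_ij[i, j], nu_i[i], size=n_c)
            measurements.extend(
                Measurement(pid, bid, cycles[k], y[k]) for k in range(n_c)
            )
    truth = SimulationTruth(
        pop=design.pop, mu_i=mu_i, sigma_i=sigma_i, tau_i=tau_i, nu_i=nu_i, mu_ij=mu_ij
    )
    return HierarchicalDataset(measurements), truth
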