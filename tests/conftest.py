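import numpy as np
import pytest

from varmeta.core_model import (
    HierarchicalDataset,
    Measurement,
    PopulationParams,
    PriorConfig,
)
from varmeta.simulate import SimulationDesign, simulate_dataset

PAPER_POP = PopulationParams(mu=0.1, sigma=0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def paper_pop():
    return PAPER_POP


@pytest.fixture
def default_prior():
    return PriorConfig()


@pytest.fixture
def single_cycle_dataset():
    """3 products x 4 batches, single cycle, deterministic."""
    design = SimulationDesign(n_products=3, n_batches=4, pop=PAPER_POP, seed=101)
    data, truth = simulate_dataset(design)
    return data, truth


@pytest.fixture
def multi_cycle_dataset():
    """4 products x 3 batches x 3 cycles at tau/nu = 1, deterministic."""
    design = SimulationDesign(
        n_products=4, n_batches=3, n_cycles=3, tau_nu_ratio=1.0,
        pop=PAPER_POP, seed=202,
    )
    data, truth = simulate_dataset(design)
    return data, truth


@pytest.fixture
def mixed_dataset(single_cycle_dataset, multi_cycle_dataset):
    """Single- and multi-cycle products merged into one dataset."""
    sc, _ = single_cycle_dataset
    mc, _ = multi_cycle_dataset
    merged = sc.measurements + [
        Measurement("M" + m.product_id, m.batch_id, m.cycle_id, m.value)
        for m in mc.measurements
    ]
    return HierarchicalDataset(merged)


@pytest.fixture
def toy_two_batch_dataset():
    """1 product, 2 single-cycle batches - the quadrature-oracle toy."""
    return HierarchicalDataset(
        [
            Measurement("A", "B1", None, 0.2),
            Measurement("A", "B2", None, 1.1),
        ]
    )
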