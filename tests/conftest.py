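import numpy as np
import pytest

from multiomesim import (SimulationConfig, builtin_tree, run_simulation,
                         synthetic_benchmark_grn)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def grn100():
    """Benchmark-scale synthetic GRN: 100 genes, 10 TFs, 150 edges."""
    return synthetic_benchmark_grn(100, 10, 150)


@pytest.fixture(scope="session")
def small_output(grn100):
    """A small but complete simulation shared across read-only tests."""
    cfg = SimulationConfig(n_cell=120, n_gene=110, seed=7)
    return run_simulation(cfg, tree=builtin_tree("phyla3"), grn=grn100)


@pytest.fixture(scope="session")
def velocity_output():
    cfg = SimulationConfig(n_cell=80, n_gene=60, seed=11, velocity=True)
    return run_simulation(cfg, tree=builtin_tree("phyla1"))
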