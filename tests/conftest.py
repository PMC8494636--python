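import numpy as np
import pandas as pd
import pytest

from epiretro import SimulationDesign, simulate_cells
from epiretro.posterior_mch import posterior_matrix


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        n_cells=240, n_bins=800, n_genes=40, coverage_mean=200,
        qc_fail_fraction=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """Default-structure synthetic dataset shared across module tests."""
    return simulate_cells(small_design)


@pytest.fixture(scope="session")
def small_posterior(small_dataset):
    matrix, table, truth = small_dataset
    bins = matrix.select_kind("bin100kb")
    M, priors = posterior_matrix(bins.mc, bins.tc, bins.cells)
    return M, bins, truth
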