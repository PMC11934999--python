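import logging

import numpy as np
import pytest

import spotmap as sm

logging.getLogger("spotmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_tissue() -> sm.SyntheticTissue:
    """4 cell types x 40 cells, 100 genes, patchy layout."""
    return sm.generate_synthetic_tissue(
        n_types=4, cells_per_type=40, n_genes=100, n_markers_per_type=8, seed=7
    )


@pytest.fixture(scope="session")
def small_st(small_tissue) -> sm.SimulatedST:
    return sm.bin_cells_to_spots(small_tissue, target_mean_cells=4.0)


@pytest.fixture(scope="session")
def small_config() -> sm.MapperConfig:
    """Light architecture so fits stay fast in unit tests."""
    return sm.MapperConfig(
        gate=sm.GateConfig(dims=(48, 12), epochs=40, lr=1e-3),
        mapping=sm.MappingConfig(epochs=400),
    )


@pytest.fixture(scope="session")
def fitted_small(small_tissue, small_st, small_config) -> sm.CellToSpotResults:
    """One fitted model shared by the contract-style tests."""
    sc_noisy = sm.perturb_expression(small_tissue.cells, 0.05, seed=8)
    model = sm.CellToSpotModel(
        sc_noisy, small_st.spots, small_st.geometry,
        annotation=small_tissue.annotation, config=small_config,
    )
    return model.fit(seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
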