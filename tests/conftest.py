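import numpy as np
import pytest

from ephyscensus import CellModelParams, extract_all, simulate_cell


@pytest.fixture(scope="session")
def quiet_params() -> CellModelParams:
    """A deterministic cell: no trace noise, no spike-time jitter."""
    return CellModelParams(noise_sd=0.0, spike_jitter=0.0)


@pytest.fixture(scope="session")
def quiet_cell(quiet_params):
    return simulate_cell(quiet_params, "quiet")


@pytest.fixture(scope="session")
def quiet_features(quiet_cell):
    return extract_all(quiet_cell)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
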