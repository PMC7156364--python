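import numpy as np
import pytest

from phantomqc import (
    AcquisitionParams,
    BlockDesign,
    preset_paper_protocol,
    simulate_series,
)


@pytest.fixture(scope="session")
def preset():
    """(geometry, acq, design, noise) of the standard QA protocol."""
    return preset_paper_protocol(seed=123)


@pytest.fixture(scope="session")
def preset_series(preset):
    """One simulated run of the full protocol with default noise."""
    geometry, acq, design, noise = preset
    return simulate_series(geometry, acq, design, noise)


@pytest.fixture(scope="session")
def quiet_series(preset):
    """Noise-free, current-free series: every volume identical."""
    geometry, acq, _, noise = preset
    design = BlockDesign(current_levels_mA=(0.0,))
    return simulate_series(geometry, acq, design, noise.silent())


@pytest.fixture(scope="session")
def fast_acq():
    """Single-slice protocol for cheap simulations."""
    return AcquisitionParams(n_slices=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
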