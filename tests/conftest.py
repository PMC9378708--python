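import numpy as np
import pytest

import finholo as fh


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tissue_field():
    """Small connected-tissue phantom shared across tests."""
    return fh.generate_phantom(fh.PhantomParams(size=(64, 64), seed=1))


@pytest.fixture
def cells_field():
    return fh.generate_phantom(
        fh.PhantomParams(kind="sparse_cells", size=(64, 64), seed=2)
    )


@pytest.fixture
def stack_m3(tissue_field):
    """Noiseless M=3 hologram stack of the tissue phantom."""
    return fh.simulate_hologram_stack(
        tissue_field, [300.0, 450.0, 600.0], fh.SensorParams(), seed=1
    )
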