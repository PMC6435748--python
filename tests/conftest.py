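import numpy as np
import pytest

from myelinquant import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """1024x1024 well, 10 well-separated ensheathing cells, low noise."""
    spec = PhantomSpec(height_px=1024, width_px=1024, n_cells=10,
                       p_ensheathing=1.0, noise_sd=0.01, seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def compact_phantom():
    """Phantom whose sheaths stay well inside a 256 px crop window.

    Short, tight length distribution so that every cell's whole arbor fits
    the crop centered on its nucleus — needed by reassembly and
    stub-inference identity checks.
    """
    spec = PhantomSpec(height_px=512, width_px=512, n_cells=8,
                       p_ensheathing=1.0, noise_sd=0.01,
                       sheaths_per_cell_mean=2.5,
                       log10_length_mean=1.3, log10_length_sd=0.1,
                       seed=7)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
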