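import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dgkit import ImagingSimParams, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact imaging session with strong place cells and ground truth."""
    params = ImagingSimParams(n_cells=8, frac_tuned=0.5, n_laps=8,
                              reliability=1.0, noise_sd=0.03)
    return simulate_session(params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
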