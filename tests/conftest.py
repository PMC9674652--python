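import numpy as np
import pytest

from dim_atlas import ABETA42, SimulationConfig, build_library


@pytest.fixture(scope="session")
def abeta_library():
    """The full designed amyloid-beta 42 library (built once per session)."""
    return build_library(ABETA42)


@pytest.fixture(scope="session")
def small_library():
    """A small complete library over a 10-residue peptide (fast fits)."""
    return build_library("MKTAYIAKQR")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def fast_sim_config():
    """Reduced-depth simulation settings for quick end-to-end tests."""
    return SimulationConfig(depth=50_000, n_bio=3, n_tech=2, seed=42)
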