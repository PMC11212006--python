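import numpy as np
import pytest

from msgea import synthetic_data as sd
from msgea import terrain


@pytest.fixture(scope="session")
def fractal_dem():
    """A moderately rugged synthetic DEM, 64x64 at 0.5 m."""
    return sd.generate_dem(64, 64, 0.5, ruggedness=1.0, trend_gradient=(0.1, 0.05), seed=42)


@pytest.fixture(scope="session")
def site_fixture():
    """A full synthetic study site (shared across pipeline-level tests).

    Smaller locus count than the headline planted-recovery conditions to
    keep unit tests quick; the acceptance suite builds the full version.
    """
    return sd.generate_fixture(seed=5, n_neutral=600, n_planted=10)


@pytest.fixture(scope="session")
def big_dem():
    """A 256x256 DEM at 0.5 m: large enough for the 16 m pyramid level."""
    return sd.generate_dem(256, 256, 0.5, ruggedness=1.5, trend_gradient=(0.1, 0.05), seed=24)


@pytest.fixture(scope="session")
def small_stack(big_dem):
    return terrain.derive_stack(
        big_dem,
        params=terrain.TerrainParams(scan_radius=10.0, scan_directions=8),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
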