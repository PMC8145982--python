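import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepoxy.chromophores import default_basis
from hepoxy.forward import ProbeGeometry, TransportConfig, run_reference_mc
from hepoxy.spectra import SpectralGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Monte Carlo seed shared by the reference records used across the suite.
MC_SEED = 20210521


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def basis(grid):
    return default_basis(grid, include_biliverdin=True)


@pytest.fixture(scope="session")
def basis_hb_only(grid):
    return default_basis(grid, include_biliverdin=False)


@pytest.fixture(scope="session")
def mc_record():
    """Reference photon record used for forward/inverse tests (white MC)."""
    return run_reference_mc(config=TransportConfig(n_photons=300_000, seed=MC_SEED))


@pytest.fixture(scope="session")
def mc_record_matched():
    """Index-matched, full-acceptance record for diffusion-theory comparison."""
    return run_reference_mc(
        geometry=ProbeGeometry(numerical_aperture=None),
        config=TransportConfig(n_photons=250_000, seed=MC_SEED, matched_boundary=True),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
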