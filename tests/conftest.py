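import numpy as np
import pytest

from fcs_hydroshape import BeamGeometry, FcsModel, PhysicalConditions, Species


@pytest.fixture(scope="session")
def beam() -> BeamGeometry:
    """Calibrated two-photon beam used throughout: ω0=0.4 µm, z0=2.0 µm (s=5)."""
    return BeamGeometry(omega0_um=0.4, z0_um=2.0, photon_mode="two-photon")


@pytest.fixture(scope="session")
def water_25C() -> PhysicalConditions:
    return PhysicalConditions(temperature_K=298.15, viscosity_cP=0.89)


@pytest.fixture(scope="session")
def single_species_model() -> FcsModel:
    return FcsModel(species=(Species(D_um2_s=84.0),), occupancy=5.0)


@pytest.fixture(scope="session")
def two_species_model() -> FcsModel:
    return FcsModel(
        species=(Species(D_um2_s=43.0, fraction=0.97), Species(D_um2_s=14.0, fraction=0.03)),
        occupancy=10.7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
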