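import numpy as np
import pytest

from nemascore.pillar_tracking import PillarArena
from nemascore.synthetic_data import StrainProfile, default_strain_panel


@pytest.fixture
def arena_small() -> PillarArena:
    """Compact 5x5 arena with default NemaFlex geometry."""
    return PillarArena(lattice_rows=5, lattice_cols=5)


@pytest.fixture
def arena_default() -> PillarArena:
    return PillarArena()


@pytest.fixture
def profile_mid() -> StrainProfile:
    """A moderately impaired strain used across generator tests."""
    return StrainProfile(
        name="mut-test", health=0.5, strength_scale=2.0, strength_cv=0.2,
        diameter_mean=60.0, diameter_cv=0.05, burrow_rate=0.03,
        burrow_success=0.6, site_bias=(1.5, 1.0, 1.0, 2.0, 1.5))


@pytest.fixture
def panel():
    return default_strain_panel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
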