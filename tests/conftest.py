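import numpy as np
import pytest

from slitdpd.builder import Configuration
from slitdpd.model import BoxGeometry, ChainSpec


@pytest.fixture
def chain() -> ChainSpec:
    return ChainSpec()


@pytest.fixture
def slit_geom() -> BoxGeometry:
    return BoxGeometry.slit(10.0, L=25.0)


def make_config(positions, species, chain_id, geometry, velocities=None, frozen=None):
    """Minimal configuration for analysis tests."""
    n = len(positions)
    return Configuration(
        positions=np.asarray(positions, dtype=float),
        velocities=np.zeros((n, 3)) if velocities is None else velocities,
        species=np.asarray(species),
        chain_id=np.asarray(chain_id),
        frozen=np.zeros(n, dtype=bool) if frozen is None else frozen,
        geometry=geometry,
    )
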