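import pandas as pd
import pytest

from metroaccess import (
    CityConfig,
    DepartureSpec,
    WalkParams,
    generate_city,
    private_od_times,
    transit_od_times,
)
from metroaccess.road_model import default_speed_model


@pytest.fixture(scope="session")
def speed_model():
    return default_speed_model()


@pytest.fixture(scope="session")
def small_config():
    """A reduced city (3 km disc, 300 m lattice) for fast structural tests."""
    return CityConfig(
        seed=11,
        addresses_per_typology=40,
        ring_radii_m=(600.0, 1200.0, 1800.0, 2400.0, 3000.0),
        road_grid_spacing_m=300.0,
        n_spokes=16,
    )


@pytest.fixture(scope="session")
def small_city(small_config):
    return generate_city(small_config)


@pytest.fixture(scope="session")
def default_city():
    """The default-configuration synthetic city (15 km disc, 200
    addresses per typology) used by the gradient-recovery checks."""
    return generate_city(CityConfig(seed=0))


@pytest.fixture(scope="session")
def default_od(default_city, speed_model):
    """Both OD matrices on the default city."""
    network, feed, facilities, addresses, _ = default_city
    od_private = private_od_times(network, speed_model, addresses, facilities)
    od_public = transit_od_times(
        network, feed, WalkParams(), DepartureSpec(), addresses, facilities
    )
    return pd.concat([od_private, od_public], ignore_index=True)
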