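"""Structure and determinism of the synthetic-city generator."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from metroaccess import CityConfig, build_typologies, generate_city, typology_of
from metroaccess.errors import ConfigError, GenerationError
from metroaccess.synthetic_city import (
    build_road_network,
    build_route_trips,
    generate_facilities,
    generate_transit_feed,
    sample_addresses,
)
from metroaccess.types import ROAD_CLASS_LABELS, SECONDARY_SERVICES, TYPOLOGY_LABELS


def radius(df):
    return np.hypot(df["x"].to_numpy(), df["y"].to_numpy())


def test_generate_city_is_deterministic(small_config):
    net1, feed1, fac1, addr1, _ = generate_city(small_config)
    net2, feed2, fac2, addr2, _ = generate_city(small_config)
    assert_frame_equal(net1.nodes, net2.nodes)
    assert_frame_equal(net1.edges, net2.edges)
    assert_frame_equal(fac1, fac2)
    assert_frame_equal(addr1, addr2)
    assert_frame_equal(feed1.stop_times, feed2.stop_times)


def test_address_counts_per_typology(small_city, small_config):
    _, _, _, addresses, _ = small_city
    counts = addresses["typology"].value_counts()
    assert len(addresses) == 5 * small_config.addresses_per_typology
    assert set(counts.index) == set(TYPOLOGY_LABELS)
    assert (counts == small_config.addresses_per_typology).all()


def test_every_point_falls_in_exactly_one_ring(small_city, small_config):
    _, _, facilities, addresses, typologies = small_city
    for df in (facilities, addresses):
        labels = typology_of(df["x"], df["y"], typologies)
        assert "outside" not in set(labels)
    # the recorded typology agrees with the geometry
    assert (
        typology_of(addresses["x"], addresses["y"], typologies)
        == addresses["typology"].to_numpy()
    ).all()


def test_facility_counts_respect_configured_rings(small_config):
    cfg = CityConfig(
        **{
            **small_config.__dict__,
            "facility_counts": {"gp": (10, 0, 0, 0, 1)},
        }
    )
    facilities = generate_facilities(cfg)
    typologies = cfg.typologies
    r = radius(facilities)
    assert (facilities["service_type"] == "gp").all()
    assert (r < typologies[0].ring_bounds[1]).sum() == 10
    assert (r >= typologies[4].ring_bounds[0]).sum() == 1


def test_secondary_facility_density_declines_outward():
    cfg = CityConfig()
    for stype in SECONDARY_SERVICES:
        counts = cfg.facility_counts[stype]
        dens = [c / t.area_m2 for c, t in zip(counts, cfg.typologies)]
        assert all(a >= b for a, b in zip(dens, dens[1:])), stype


def test_sampled_addresses_are_deterministic_and_contained():
    typologies = build_typologies((500.0, 900.0, 1300.0, 1700.0, 2000.0))
    a1 = sample_addresses(typologies, 50, seed=3)
    a2 = sample_addresses(typologies, 50, seed=3)
    assert_frame_equal(a1, a2)
    for t in typologies:
        pts = a1[a1["typology"] == t.label]
        assert len(pts) == 50
        r = radius(pts)
        assert ((r >= t.ring_bounds[0]) & (r < t.ring_bounds[1])).all()


def test_study_scale_sample_has_fifty_thousand_points():
    """At the full study scale of 10,000 addresses per typology the
    sample reaches ~50,000 synthetic residential points."""
    typologies = build_typologies((3000.0, 6000.0, 9000.0, 12000.0, 15000.0))
    sample = sample_addresses(typologies, 10_000, seed=0)
    assert len(sample) == 50_000


class _FakeRing:
    def __init__(self, label, bounds):
        self.label = label
        self.ring_bounds = bounds


def test_empty_ring_is_rejected_by_name():
    rings = [_FakeRing("inner", (0.0, 500.0)), _FakeRing("middle", (900.0, 900.0))]
    with pytest.raises(GenerationError, match="middle"):
        sample_addresses(rings, 10, seed=0)


@pytest.mark.parametrize(
    "bad_kwargs",
    [
        {"ring_radii_m": (3000.0, 2000.0, 9000.0, 12000.0, 15000.0)},
        {"facility_counts": {"gp": (1, 1, 1, 1, -1)}},
        {"transit_headway_min": {"train": 0.0}},
        {"road_grid_spacing_m": -5.0},
    ],
)
def test_invalid_configs_rejected(bad_kwargs):
    with pytest.raises(ConfigError):
        CityConfig(**bad_kwargs).validate()


def test_all_five_road_classes_present_in_every_ring(small_config):
    network = build_road_network(small_config)
    typologies = small_config.typologies
    coords = network.nodes.set_index("node_id")
    mid_x = (
        coords.loc[network.edges["from_node"], "x"].to_numpy()
        + coords.loc[network.edges["to_node"], "x"].to_numpy()
    ) / 2
    mid_y = (
        coords.loc[network.edges["from_node"], "y"].to_numpy()
        + coords.loc[network.edges["to_node"], "y"].to_numpy()
    ) / 2
    ring = typology_of(mid_x, mid_y, typologies)
    for t in typologies:
        present = set(network.edges.loc[ring == t.label, "road_class"])
        assert present == set(ROAD_CLASS_LABELS), t.label


def test_transit_stops_lie_on_road_nodes(small_city):
    network, feed, _, _, _ = small_city
    node_xy = network.nodes.set_index("node_id")[["x", "y"]]
    snapped = network.snap_points(feed.stops["x"], feed.stops["y"])
    dx = feed.stops["x"].to_numpy() - node_xy.loc[snapped, "x"].to_numpy()
    dy = feed.stops["y"].to_numpy() - node_xy.loc[snapped, "y"].to_numpy()
    assert np.hypot(dx, dy).max() < 1e-6


def test_stop_times_strictly_increase_along_each_trip(small_city):
    _, feed, _, _, _ = small_city
    st = feed.stop_times.sort_values(["trip_id", "stop_sequence"])
    for _, grp in st.groupby("trip_id"):
        arr = grp["arrival_s"].to_numpy()
        dep = grp["departure_s"].to_numpy()
        assert (dep >= arr).all()
        assert (arr[1:] > dep[:-1]).all()


def test_trip_count_follows_window_over_headway():
    """A 2-hour window at a 10-minute headway produces 12 departures."""
    trips, stop_times = build_route_trips(
        "r1", [0, 1], [360], headway_s=600.0, window_s=(11 * 3600, 13 * 3600)
    )
    assert len(trips) == 12
    first = stop_times[stop_times["trip_id"] == trips["trip_id"].iloc[0]]
    assert first["departure_s"].iloc[0] == 11 * 3600


def test_non_dividing_headway_rounds_down_never_errors():
    trips, _ = build_route_trips(
        "r1", [0, 1], [60], headway_s=7 * 60.0, window_s=(0, 3600)
    )
    # 3600 / 420 = 8.57... -> 9 departures fit strictly before the hour
    assert len(trips) == 9


def test_service_active_on_wednesday(small_city):
    _, feed, _, _, _ = small_city
    assert len(feed.trips_active_on("wednesday")) == len(feed.trips)
    assert len(feed.trips_active_on("sunday")) == 0


def test_transit_requires_nonempty_network(small_config):
    empty = build_road_network(small_config)
    empty.nodes = empty.nodes.iloc[:0]
    with pytest.raises(GenerationError):
        generate_transit_feed(empty, small_config)
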