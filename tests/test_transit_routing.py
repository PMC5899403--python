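"""Multimodal earliest-arrival routing: fixtures, invariants, and the
exhaustive journey-enumeration oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from metroaccess import DepartureSpec, WalkParams, journey_time, load_gtfs, transit_od_times
from metroaccess.errors import FeedError
from metroaccess.io import write_gtfs
from metroaccess.transit_model import TransitRouter, parse_gtfs_time, format_gtfs_time

from helpers import (
    addresses_at,
    empty_feed_like,
    journey_minutes_oracle,
    line_network,
    make_feed,
    single_type_facilities,
)

NOON = DepartureSpec(weekday="wednesday", depart_s=12 * 3600)
WALK5 = WalkParams(walk_speed_kmh=5.0)


def hhmm(h, m=0, s=0):
    return h * 3600 + m * 60 + s


@pytest.fixture()
def bus_fixture():
    """Two stops 5 km apart (60 min walk); one bus leaves 12:04, arrives 12:10."""
    net = line_network(2, 5000.0)
    feed = make_feed(
        stops={"S1": (0.0, 0.0), "S2": (5000.0, 0.0)},
        trips={"t1": [("S1", hhmm(12, 4), hhmm(12, 4)), ("S2", hhmm(12, 10), hhmm(12, 10))]},
    )
    return net, feed


def test_gtfs_time_round_trip():
    assert parse_gtfs_time("25:03:07") == 25 * 3600 + 187
    assert format_gtfs_time(parse_gtfs_time("07:30:00")) == "07:30:00"
    with pytest.raises(FeedError):
        parse_gtfs_time("noonish")


def test_identity_journey_is_zero(bus_fixture):
    net, feed = bus_fixture
    assert journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (0.0, 0.0)) == 0.0


def test_bus_journey_includes_initial_wait(bus_fixture):
    """4 min wait + 6 min ride beats the 60 min walk: 10 min total."""
    net, feed = bus_fixture
    assert journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (5000.0, 0.0)) == pytest.approx(10.0)


def test_walk_only_when_no_useful_transit():
    """500 m at 5 km/h with no boardable trip takes 6 minutes on foot."""
    net = line_network(3, 250.0)
    feed = make_feed(
        stops={"S1": (0.0, 0.0), "S2": (500.0, 0.0)},
        trips={"t1": [("S1", hhmm(9), hhmm(9)), ("S2", hhmm(9, 5), hhmm(9, 5))]},
    )  # departs long before noon
    assert journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (500.0, 0.0)) == pytest.approx(6.0)


def test_journey_never_exceeds_pure_walk(bus_fixture):
    net, feed = bus_fixture
    for depart_s in (hhmm(11, 50), hhmm(12, 3), hhmm(12, 5), hhmm(13)):
        spec = DepartureSpec(weekday="wednesday", depart_s=depart_s)
        t = journey_time(net, feed, WALK5, spec, (0.0, 0.0), (5000.0, 0.0))
        assert t <= 60.0 + 1e-9


def test_boarding_allowed_at_exact_departure_second(bus_fixture):
    net, feed = bus_fixture
    spec = DepartureSpec(weekday="wednesday", depart_s=hhmm(12, 4))
    assert journey_time(net, feed, WALK5, spec, (0.0, 0.0), (5000.0, 0.0)) == pytest.approx(6.0)


def test_missed_departure_strictly_increases_journey(bus_fixture):
    net, feed = bus_fixture
    before = journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (5000.0, 0.0))
    after = journey_time(
        net, feed, WALK5,
        DepartureSpec(weekday="wednesday", depart_s=hhmm(12, 4) + 1),
        (0.0, 0.0), (5000.0, 0.0),
    )
    assert after > before  # only the walk remains


def test_fifo_arrival_nondecreasing_in_departure(bus_fixture):
    net, feed = bus_fixture
    arrivals = []
    for depart_s in range(hhmm(11, 55), hhmm(12, 15), 60):
        spec = DepartureSpec(weekday="wednesday", depart_s=depart_s)
        t = journey_time(net, feed, WALK5, spec, (0.0, 0.0), (5000.0, 0.0))
        arrivals.append(depart_s + t * 60.0)
    assert all(a <= b + 1e-9 for a, b in zip(arrivals, arrivals[1:]))


def test_trip_inactive_on_wednesday_is_excluded():
    net = line_network(2, 5000.0)
    feed = make_feed(
        stops={"S1": (0.0, 0.0), "S2": (5000.0, 0.0)},
        trips={
            "wed@weekday": [("S1", hhmm(12, 4), hhmm(12, 4)), ("S2", hhmm(12, 10), hhmm(12, 10))],
            "sat@weekend": [("S1", hhmm(12, 1), hhmm(12, 1)), ("S2", hhmm(12, 5), hhmm(12, 5))],
        },
        calendar_days={
            "weekday": ("monday", "tuesday", "wednesday", "thursday", "friday"),
            "weekend": ("saturday", "sunday"),
        },
    )
    # the Saturday express would arrive 12:05; on Wednesday only 12:10 works
    assert journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (5000.0, 0.0)) == pytest.approx(10.0)
    sat = DepartureSpec(weekday="saturday", depart_s=NOON.depart_s)
    assert journey_time(net, feed, WALK5, sat, (0.0, 0.0), (5000.0, 0.0)) == pytest.approx(5.0)


def test_transfer_between_trips():
    """Two legs with a feasible connection at the middle stop."""
    net = line_network(3, 4000.0)
    feed = make_feed(
        stops={"A": (0.0, 0.0), "B": (4000.0, 0.0), "C": (8000.0, 0.0)},
        trips={
            "t1": [("A", hhmm(12, 2), hhmm(12, 2)), ("B", hhmm(12, 8), hhmm(12, 8))],
            "t2": [("B", hhmm(12, 8), hhmm(12, 8)), ("C", hhmm(12, 15), hhmm(12, 15))],
        },
    )
    # board t2 at its exact departure upon alighting t1
    assert journey_time(net, feed, WALK5, NOON, (0.0, 0.0), (8000.0, 0.0)) == pytest.approx(15.0)


def test_empty_feed_reduces_to_walk_od(small_city, speed_model):
    network, feed, facilities, addresses, _ = small_city
    no_transit = empty_feed_like(feed)
    od = transit_od_times(network, no_transit, WALK5, NOON, addresses, facilities)
    # oracle: walk is driving on a uniform "speed model" at walking speed
    from metroaccess.road_model import private_od_times
    from metroaccess.types import ROAD_CLASS_LABELS, SpeedModel

    walk_model = SpeedModel({c: WALK5.walk_speed_kmh for c in ROAD_CLASS_LABELS})
    walk_od = private_od_times(network, walk_model, addresses, facilities)
    merged = od.merge(
        walk_od, on=["address_id", "service_type"], suffixes=("_transit", "_walk")
    )
    assert np.allclose(merged["minutes_transit"], merged["minutes_walk"], atol=1e-6)


def test_transit_od_never_slower_than_walk_od(small_city):
    network, feed, facilities, addresses, _ = small_city
    with_transit = transit_od_times(network, feed, WALK5, NOON, addresses, facilities)
    without = transit_od_times(
        network, empty_feed_like(feed), WALK5, NOON, addresses, facilities
    )
    merged = with_transit.merge(
        without, on=["address_id", "service_type"], suffixes=("_t", "_w")
    )
    assert (merged["minutes_t"] <= merged["minutes_w"] + 1e-9).all()


def test_colocated_facilities_give_zero(bus_fixture):
    net, feed = bus_fixture
    od = transit_od_times(
        net, feed, WALK5, NOON,
        addresses_at([(0.0, 0.0)]), single_type_facilities([(0.0, 0.0)]),
    )
    assert od["minutes"].iloc[0] == 0.0


@pytest.mark.parametrize("seed", range(12))
def test_matches_enumeration_oracle_on_random_small_feeds(seed):
    """Connection-scan earliest arrival equals exhaustive journey
    enumeration on random feeds with <= 5 stops and <= 3 trips."""
    rng = np.random.default_rng(seed)
    n_stops = int(rng.integers(2, 6))
    net = line_network(n_stops, float(rng.integers(300, 3000)))
    stop_ids = [f"S{i}" for i in range(n_stops)]
    stops = {s: (float(net.nodes["x"][i]), 0.0) for i, s in enumerate(stop_ids)}
    trips = {}
    for k in range(int(rng.integers(1, 4))):
        a, b = sorted(rng.choice(n_stops, size=2, replace=False))
        path = stop_ids[a:b + 1]
        t = int(rng.integers(hhmm(11, 50), hhmm(12, 40)))
        seq = []
        for s in path:
            seq.append((s, t, t))
            t += int(rng.integers(30, 600))
        trips[f"t{k}"] = seq
    feed = make_feed(stops=stops, trips=trips)
    for origin, dest in [(stop_ids[0], stop_ids[-1]), (stop_ids[-1], stop_ids[0])]:
        expected = journey_minutes_oracle(
            net, feed, 5.0, "wednesday", NOON.depart_s, origin, dest
        )
        got = journey_time(net, feed, WALK5, NOON, stops[origin], stops[dest])
        assert got == pytest.approx(expected, abs=1e-9), (origin, dest, trips)


def test_max_walk_cap_can_disconnect():
    net = line_network(2, 5000.0)
    feed = make_feed(
        stops={"S1": (0.0, 0.0), "S2": (5000.0, 0.0)},
        trips={"t1": [("S1", hhmm(9), hhmm(9)), ("S2", hhmm(9, 5), hhmm(9, 5))]},
    )
    capped = WalkParams(walk_speed_kmh=5.0, max_access_walk_m=1000.0)
    t = journey_time(net, feed, capped, NOON, (0.0, 0.0), (5000.0, 0.0))
    assert math.isinf(t)


# ---------------------------------------------------------------------------
# GTFS loading errors

def test_round_trip_write_then_load(small_city, tmp_path):
    _, feed, _, _, _ = small_city
    write_gtfs(feed, str(tmp_path))
    loaded = load_gtfs(str(tmp_path))
    left = feed.stop_times.sort_values(["trip_id", "stop_sequence"]).reset_index(drop=True)
    right = loaded.stop_times.sort_values(["trip_id", "stop_sequence"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(left, right, check_dtype=False)
    merged = feed.stops.merge(loaded.stops, on="stop_id", suffixes=("_a", "_b"))
    assert np.allclose(merged[["x_a", "y_a"]], merged[["x_b", "y_b"]], atol=1e-6)
    assert set(loaded.trips_active_on("wednesday")["trip_id"]) == set(
        feed.trips_active_on("wednesday")["trip_id"]
    )


def test_missing_file_is_a_feed_error(small_city, tmp_path):
    _, feed, _, _, _ = small_city
    write_gtfs(feed, str(tmp_path))
    (tmp_path / "calendar.txt").unlink()
    with pytest.raises(FeedError, match="calendar.txt"):
        load_gtfs(str(tmp_path))


def test_dangling_stop_reference_is_an_error(small_city, tmp_path):
    _, feed, _, _, _ = small_city
    write_gtfs(feed, str(tmp_path))
    st = pd.read_csv(tmp_path / "stop_times.txt")
    st.loc[0, "stop_id"] = "S_GHOST"
    st.to_csv(tmp_path / "stop_times.txt", index=False)
    with pytest.raises(FeedError, match="stop_id"):
        load_gtfs(str(tmp_path))


def test_non_monotone_stop_times_rejected_with_trip_name(small_city, tmp_path):
    _, feed, _, _, _ = small_city
    write_gtfs(feed, str(tmp_path))
    st = pd.read_csv(tmp_path / "stop_times.txt")
    trip = st["trip_id"].iloc[0]
    rows = st["trip_id"] == trip
    st.loc[rows & (st["stop_sequence"] == 1), ["arrival_time", "departure_time"]] = "00:00:01"
    st.to_csv(tmp_path / "stop_times.txt", index=False)
    with pytest.raises(FeedError, match=trip.replace("#", "\\#")):
        load_gtfs(str(tmp_path))
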