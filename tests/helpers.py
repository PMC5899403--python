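"""Independent oracles and fixture builders for the test suite.

The routing oracles here deliberately use different algorithms from the
package: dense Floyd-Warshall for road shortest times, and a round-based
fixed-point enumeration over ride legs for multimodal earliest arrival.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall

from metroaccess.types import ROAD_CLASS_LABELS, RoadNetwork, TransitFeed


# ---------------------------------------------------------------------------
# Road-network oracle

def random_road_network(rng: np.random.Generator, n_nodes: int, n_edges: int) -> RoadNetwork:
    """Random classed network; not necessarily connected."""
    xy = rng.uniform(-5000, 5000, size=(n_nodes, 2))
    nodes = pd.DataFrame({"node_id": np.arange(n_nodes), "x": xy[:, 0], "y": xy[:, 1]})
    rows = []
    for _ in range(n_edges):
        a, b = rng.integers(0, n_nodes, size=2)
        if a == b:
            continue
        rows.append(
            (
                int(a),
                int(b),
                float(rng.uniform(50, 3000)),
                ROAD_CLASS_LABELS[rng.integers(0, len(ROAD_CLASS_LABELS))],
            )
        )
    if not rows:  # guarantee at least one edge between distinct nodes
        rows.append((0, 1 % n_nodes, 100.0, "local"))
    edges = pd.DataFrame(rows, columns=["from_node", "to_node", "length_m", "road_class"])
    return RoadNetwork(nodes=nodes, edges=edges).validate()


def _dense_min_matrix(n: int, triples) -> np.ndarray:
    """Dense adjacency keeping the minimum over parallel edges."""
    mat = np.full((n, n), np.inf)
    for a, b, w in triples:
        if w < mat[a, b]:
            mat[a, b] = mat[b, a] = w
    np.fill_diagonal(mat, 0.0)
    return mat


def floyd_warshall_minutes(network: RoadNetwork, model) -> np.ndarray:
    """All-pairs shortest driving minutes by dense Floyd-Warshall."""
    from metroaccess.road_model import edge_travel_time

    n = len(network.nodes)
    triples = (
        (e.from_node, e.to_node, edge_travel_time(e.length_m, e.road_class, model))
        for e in network.edges.itertuples(index=False)
    )
    return floyd_warshall(_dense_min_matrix(n, triples), directed=True)


# ---------------------------------------------------------------------------
# Transit enumeration oracle

def feed_connections(
    feed: TransitFeed, weekday: str
) -> List[Tuple[str, str, int, int]]:
    """(board stop, alight stop, departure_s, arrival_s) per consecutive
    stop pair of every trip active on the weekday."""
    active = set(feed.trips_active_on(weekday)["trip_id"])
    conns = []
    st = feed.stop_times.sort_values(["trip_id", "stop_sequence"])
    for trip_id, grp in st.groupby("trip_id", sort=False):
        if trip_id not in active:
            continue
        stops = grp["stop_id"].tolist()
        arr = grp["arrival_s"].tolist()
        dep = grp["departure_s"].tolist()
        for i in range(len(stops) - 1):
            conns.append((stops[i], stops[i + 1], dep[i], arr[i + 1]))
    return conns


def enumerate_earliest_arrival(
    feed: TransitFeed,
    weekday: str,
    depart_s: float,
    walk_s: Dict[Tuple[str, str], float],
    stop_ids: Sequence[str],
    origin_stop: str,
    dest_stop: str,
    max_rides: int = 6,
) -> float:
    """Earliest arrival at ``dest_stop`` by exhaustive round expansion.

    Round k holds the best arrival using at most k vehicle legs, each
    preceded/followed by an optional walk; iterating to a fixed point (or
    ``max_rides``) enumerates every feasible journey shape.
    ``walk_s[(a, b)]`` is the walking time between stops (inf if impossible).
    """
    conns = feed_connections(feed, weekday)
    best = {s: depart_s + walk_s[(origin_stop, s)] for s in stop_ids}
    for _ in range(max_rides):
        nxt = dict(best)
        for a, b, dep, arr in conns:
            if best[a] <= dep:
                for s in stop_ids:
                    cand = arr + walk_s[(b, s)]
                    if cand < nxt[s]:
                        nxt[s] = cand
        if nxt == best:
            break
        best = nxt
    return best[dest_stop]


# ---------------------------------------------------------------------------
# Small fixture builders

def line_network(n_nodes: int, spacing_m: float, road_class: str = "local") -> RoadNetwork:
    """Nodes 0..n-1 on a line, consecutive nodes joined by one edge."""
    nodes = pd.DataFrame(
        {"node_id": range(n_nodes), "x": [i * spacing_m for i in range(n_nodes)],
         "y": [0.0] * n_nodes}
    )
    edges = pd.DataFrame(
        {
            "from_node": range(n_nodes - 1),
            "to_node": range(1, n_nodes),
            "length_m": [spacing_m] * (n_nodes - 1),
            "road_class": [road_class] * (n_nodes - 1),
        }
    )
    return RoadNetwork(nodes=nodes, edges=edges).validate()


def make_feed(
    stops: Dict[str, Tuple[float, float]],
    trips: Dict[str, List[Tuple[str, int, int]]],
    modes: Dict[str, str] | None = None,
    calendar_days: Dict[str, Sequence[str]] | None = None,
) -> TransitFeed:
    """Hand-build a feed.  ``trips`` maps trip_id -> [(stop, arr_s, dep_s)];
    route/service ids default to one weekday-only service per trip's route
    ``r_<trip>`` unless overridden via ``calendar_days`` (service -> days)."""
    from metroaccess.types import WEEKDAYS

    stops_df = pd.DataFrame(
        [(sid, sid, x, y) for sid, (x, y) in stops.items()],
        columns=["stop_id", "stop_name", "x", "y"],
    )
    modes = modes or {}
    calendar_days = calendar_days or {"weekday": WEEKDAYS[:5]}
    trip_rows, st_rows, route_rows = [], [], []
    for trip_id, seq in trips.items():
        route_id = f"r_{trip_id}"
        service_id = list(calendar_days)[0] if "@" not in trip_id else trip_id.split("@")[1]
        trip_rows.append((trip_id, route_id, service_id))
        route_rows.append((route_id, modes.get(trip_id, "bus")))
        for k, (stop, arr, dep) in enumerate(seq):
            st_rows.append((trip_id, k, stop, arr, dep))
    cal_rows = []
    for service_id, days in calendar_days.items():
        cal_rows.append(
            {"service_id": service_id, **{d: (1 if d in days else 0) for d in WEEKDAYS}}
        )
    feed = TransitFeed(
        stops=stops_df,
        routes=pd.DataFrame(route_rows, columns=["route_id", "mode"]).drop_duplicates(),
        trips=pd.DataFrame(trip_rows, columns=["trip_id", "route_id", "service_id"]),
        stop_times=pd.DataFrame(
            st_rows,
            columns=["trip_id", "stop_sequence", "stop_id", "arrival_s", "departure_s"],
        ),
        calendar=pd.DataFrame(cal_rows),
    )
    return feed.validate()


def empty_feed_like(feed: TransitFeed) -> TransitFeed:
    """Same stops/calendar, no trips at all."""
    return TransitFeed(
        stops=feed.stops,
        routes=feed.routes.iloc[:0],
        trips=feed.trips.iloc[:0],
        stop_times=feed.stop_times.iloc[:0],
        calendar=feed.calendar,
    ).validate()


def single_type_facilities(
    xy: Sequence[Tuple[float, float]], service_type: str = "gp"
) -> pd.DataFrame:
    from metroaccess.types import TIER_BY_SERVICE

    return pd.DataFrame(
        [
            (f"{service_type}_{i:04d}", x, y, service_type, TIER_BY_SERVICE[service_type])
            for i, (x, y) in enumerate(xy)
        ],
        columns=["facility_id", "x", "y", "service_type", "tier"],
    )


def addresses_at(xy: Sequence[Tuple[float, float]], typology: str = "inner") -> pd.DataFrame:
    return pd.DataFrame(
        [(i, x, y, typology) for i, (x, y) in enumerate(xy)],
        columns=["address_id", "x", "y", "typology"],
    )


def assert_finite_minutes(od: pd.DataFrame) -> None:
    assert np.isfinite(od["minutes"]).all(), "unexpected unreachable cells"


def walk_seconds_between_stops(
    network: RoadNetwork, feed: TransitFeed, walk_speed_kmh: float
) -> Dict[Tuple[str, str], float]:
    """Walking seconds between every stop pair over the road network,
    for the enumeration oracle (independent dense Floyd-Warshall)."""
    n = len(network.nodes)
    triples = (
        (e.from_node, e.to_node, e.length_m) for e in network.edges.itertuples(index=False)
    )
    dist = floyd_warshall(_dense_min_matrix(n, triples), directed=True)
    mps = walk_speed_kmh / 3.6
    snap = network.snap_points(feed.stops["x"], feed.stops["y"])
    node_of = dict(zip(feed.stops["stop_id"], snap))
    out = {}
    for a in feed.stops["stop_id"]:
        for b in feed.stops["stop_id"]:
            out[(a, b)] = dist[node_of[a], node_of[b]] / mps
    return out


def journey_minutes_oracle(
    network: RoadNetwork,
    feed: TransitFeed,
    walk_speed_kmh: float,
    weekday: str,
    depart_s: float,
    origin_stop: str,
    dest_stop: str,
) -> float:
    walk = walk_seconds_between_stops(network, feed, walk_speed_kmh)
    arr = enumerate_earliest_arrival(
        feed, weekday, depart_s, walk, list(feed.stops["stop_id"]), origin_stop, dest_stop
    )
    if math.isinf(arr):
        return math.inf
    return (arr - depart_s) / 60.0
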