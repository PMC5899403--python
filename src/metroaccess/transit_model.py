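"""Multimodal public-transport routing: GTFS parsing and earliest-arrival
journey times from a fixed departure instant.

A journey is any alternation of walking legs (over the road network at a
constant walk speed) and timetabled vehicle legs, boarded no earlier than
their scheduled departure (boarding at the exact departure second is
allowed).  The answer for an origin-destination pair is the earliest
arrival at the destination minus the departure instant, including any
initial wait; pure walking is always admissible, so a journey time never
exceeds the walk-only shortest time.

The solver scans ride connections (consecutive stop pairs within a trip)
in departure order, maintaining the earliest-known arrival at every road
node; each improving connection relaxes walking transfers to all nodes at
once through a precomputed all-pairs walking-time matrix.  Scanning in
departure order makes a single pass sufficient: a connection is boardable
iff the earliest arrival at its departure stop does not exceed its
departure time, and staying aboard a vehicle is recovered by boarding the
trip's next connection (departure >= arrival, zero transfer penalty).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import FeedError
from .types import (
    DepartureSpec,
    GTFS_FILES,
    ROUTE_TYPE_TO_MODE,
    RoadNetwork,
    TransitFeed,
    WalkParams,
    WEEKDAYS,
)

logger = logging.getLogger(__name__)

UNREACHABLE = math.inf


# ---------------------------------------------------------------------------
# GTFS loading

def parse_gtfs_time(text: str) -> int:
    """HH:MM:SS (hours may exceed 24) -> seconds after midnight."""
    try:
        h, m, s = text.strip().split(":")
        return int(h) * 3600 + int(m) * 60 + int(s)
    except (ValueError, AttributeError) as exc:
        raise FeedError(f"malformed GTFS time {text!r}") from exc


def format_gtfs_time(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def load_gtfs(path: str) -> TransitFeed:
    """Read a minimal GTFS directory into a validated :class:`TransitFeed`.

    Requires stops.txt, routes.txt, trips.txt, stop_times.txt and
    calendar.txt.  Stop coordinates are taken from stop_lon/stop_lat,
    interpreted as planar metres (x, y).  Trips with non-monotone stop
    times or dangling ids are rejected with context.
    """
    tables = {}
    for fname in GTFS_FILES:
        fpath = os.path.join(path, fname)
        if not os.path.exists(fpath):
            raise FeedError(f"missing GTFS file: {fname}")
        tables[fname] = pd.read_csv(fpath, dtype=str, skipinitialspace=True)

    stops_raw = tables["stops.txt"]
    stops = pd.DataFrame(
        {
            "stop_id": stops_raw["stop_id"],
            "stop_name": stops_raw.get("stop_name", stops_raw["stop_id"]),
            "x": stops_raw["stop_lon"].astype(float),
            "y": stops_raw["stop_lat"].astype(float),
        }
    )
    routes_raw = tables["routes.txt"]
    routes = pd.DataFrame(
        {
            "route_id": routes_raw["route_id"],
            "mode": routes_raw["route_type"].astype(int).map(
                lambda t: ROUTE_TYPE_TO_MODE.get(t, "other")
            ),
        }
    )
    trips = tables["trips.txt"][["trip_id", "route_id", "service_id"]].copy()
    st_raw = tables["stop_times.txt"]
    stop_times = pd.DataFrame(
        {
            "trip_id": st_raw["trip_id"],
            "stop_sequence": st_raw["stop_sequence"].astype(int),
            "stop_id": st_raw["stop_id"],
            "arrival_s": st_raw["arrival_time"].map(parse_gtfs_time),
            "departure_s": st_raw["departure_time"].map(parse_gtfs_time),
        }
    )
    cal_raw = tables["calendar.txt"]
    calendar = pd.DataFrame({"service_id": cal_raw["service_id"]})
    for day in WEEKDAYS:
        calendar[day] = cal_raw[day].astype(int)

    feed = TransitFeed(
        stops=stops, routes=routes, trips=trips, stop_times=stop_times, calendar=calendar
    )
    return feed.validate()


# ---------------------------------------------------------------------------
# Routing

def walk_time_matrix(
    network: RoadNetwork, walk: WalkParams
) -> Tuple[np.ndarray, np.ndarray, Dict[int, int]]:
    """All-pairs walking times (seconds) between road nodes.

    Returns (node_ids, matrix, node_id -> row index).  When
    ``max_access_walk_m`` is set, pairs farther apart than the cap (by
    network distance) are +inf.
    """
    ids, _ = network.node_xy()
    index = {int(n): i for i, n in enumerate(ids)}
    n = len(ids)
    # collapse parallel edges to the shortest before building the matrix
    shortest = (
        network.edges.assign(
            a=network.edges["from_node"].map(index), b=network.edges["to_node"].map(index)
        )
        .groupby(["a", "b"], as_index=False)["length_m"]
        .min()
    )
    dist_m = _csgraph_dijkstra(
        csr_matrix(
            (shortest["length_m"], (shortest["a"], shortest["b"])), shape=(n, n)
        ),
        directed=False,
    )
    if walk.max_access_walk_m is not None:
        dist_m = np.where(dist_m <= walk.max_access_walk_m, dist_m, np.inf)
    return ids, dist_m / walk.walk_speed_mps, index


@dataclass
class TransitRouter:
    """Precomputed structures for repeated earliest-arrival queries.

    Built once per (network, feed, walk parameters, weekday); queries are
    per origin node and departure second.
    """

    node_ids: np.ndarray
    walk_s: np.ndarray                 # all-pairs walking seconds
    node_index: Dict[int, int]
    conn_dep_node: np.ndarray          # row index of each connection's boarding node
    conn_arr_node: np.ndarray
    conn_dep_s: np.ndarray             # sorted ascending
    conn_arr_s: np.ndarray

    @classmethod
    def build(
        cls,
        network: RoadNetwork,
        feed: TransitFeed,
        walk: WalkParams,
        depart: DepartureSpec,
    ) -> "TransitRouter":
        ids, walk_s, index = walk_time_matrix(network, walk)
        stop_nodes = dict(
            zip(
                feed.stops["stop_id"],
                network.snap_points(feed.stops["x"], feed.stops["y"]),
            )
        )
        active = set(feed.trips_active_on(depart.weekday)["trip_id"])
        st = feed.stop_times[feed.stop_times["trip_id"].isin(active)]
        st = st.sort_values(["trip_id", "stop_sequence"])
        dep_node, arr_node, dep_s, arr_s = [], [], [], []
        for _, grp in st.groupby("trip_id", sort=False):
            nodes = [index[int(stop_nodes[s])] for s in grp["stop_id"]]
            a = grp["arrival_s"].to_numpy()
            d = grp["departure_s"].to_numpy()
            dep_node.extend(nodes[:-1])
            arr_node.extend(nodes[1:])
            dep_s.extend(d[:-1])
            arr_s.extend(a[1:])
        order = np.argsort(np.asarray(dep_s, dtype=float), kind="stable")
        logger.info(
            "transit router: %d nodes, %d connections active on %s",
            len(ids), len(order), depart.weekday,
        )
        return cls(
            node_ids=ids,
            walk_s=walk_s,
            node_index=index,
            conn_dep_node=np.asarray(dep_node, dtype=int)[order],
            conn_arr_node=np.asarray(arr_node, dtype=int)[order],
            conn_dep_s=np.asarray(dep_s, dtype=float)[order],
            conn_arr_s=np.asarray(arr_s, dtype=float)[order],
        )

    def earliest_arrivals(self, origin_node: int, depart_s: float) -> np.ndarray:
        """Earliest clock arrival (seconds) at every road node.

        Initialised by walking from the origin; each boardable connection
        (earliest arrival at its boarding node <= its departure) then
        relaxes its alighting node and, through the walk matrix, every
        node reachable on foot from it.
        """
        o = self.node_index[int(origin_node)]
        ea = depart_s + self.walk_s[o].copy()
        start = int(np.searchsorted(self.conn_dep_s, depart_s, side="left"))
        dep_node, arr_node = self.conn_dep_node, self.conn_arr_node
        dep_s, arr_s = self.conn_dep_s, self.conn_arr_s
        walk_s = self.walk_s
        for k in range(start, len(dep_s)):
            if ea[dep_node[k]] <= dep_s[k] and arr_s[k] < ea[arr_node[k]]:
                np.minimum(ea, arr_s[k] + walk_s[arr_node[k]], out=ea)
        return ea


def journey_time(
    network: RoadNetwork,
    feed: TransitFeed,
    walk: WalkParams,
    depart: DepartureSpec,
    origin: Tuple[float, float],
    dest: Tuple[float, float],
    router: Optional[TransitRouter] = None,
) -> float:
    """Earliest-arrival journey time in minutes between two points.

    Both points snap to their nearest road node.  Returns +inf when
    neither walking nor transit can connect them (possible only with a
    walking-distance cap on a disconnected network).
    """
    router = router or TransitRouter.build(network, feed, walk, depart)
    o = network.snap_points([origin[0]], [origin[1]])[0]
    d = network.snap_points([dest[0]], [dest[1]])[0]
    ea = router.earliest_arrivals(int(o), float(depart.depart_s))
    arrival = ea[router.node_index[int(d)]]
    return (arrival - depart.depart_s) / 60.0


def transit_od_times(
    network: RoadNetwork,
    feed: TransitFeed,
    walk: WalkParams,
    depart: DepartureSpec,
    origins: pd.DataFrame,
    destinations: pd.DataFrame,
) -> pd.DataFrame:
    """Public-transport minutes from every address to its nearest facility
    of each service type (mode ``"public"``).

    Earliest-arrival queries are computed once per distinct snapped origin
    node and shared by all addresses snapping there.
    """
    from .road_model import od_times_from_nearest  # shared OD assembly
    from .types import validate_addresses, validate_facilities

    validate_addresses(origins)
    validate_facilities(destinations)
    router = TransitRouter.build(network, feed, walk, depart)
    origin_nodes = network.snap_points(origins["x"], origins["y"])
    fac_nodes = destinations.assign(
        node=network.snap_points(destinations["x"], destinations["y"])
    )
    fac_rows_by_type = {
        stype: np.array([router.node_index[int(n)] for n in grp["node"]], dtype=int)
        for stype, grp in fac_nodes.groupby("service_type", sort=True)
    }
    # one earliest-arrival sweep per distinct origin node
    best: Dict[str, Dict[int, float]] = {s: {} for s in fac_rows_by_type}
    for node in sorted(set(int(n) for n in origin_nodes)):
        ea = router.earliest_arrivals(node, float(depart.depart_s))
        for stype, rows in fac_rows_by_type.items():
            if len(rows) == 0:
                continue
            t = float(ea[rows].min())
            if math.isfinite(t):
                best[stype][node] = (t - depart.depart_s) / 60.0
    return od_times_from_nearest(origins, origin_nodes, best, "public")
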