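"""Seeded generator of a toy metropolitan area.

The synthetic city is a disc partitioned into five concentric annuli (the
area typologies).  Its road network is a polar lattice: a small number of
major radial spokes (alternating freeway / arterial), orbital sub-arterial
ring roads at every grid radius, and minor infill radials (alternating
collector / local) between the majors, so every annulus contains all five
road-hierarchy classes.  Trains run along the freeway spokes, stopping at
every ring; one orbital bus route serves each annulus, stopping where it
crosses a major spoke, with headways lengthening outward — the
transit-coverage gradient of a real metropolitan area.  Facility density per unit area declines from the centre outward,
most sharply for referral-based (secondary) services.  Addresses are drawn
uniformly over each annulus.

Randomness uses one root seed with fixed per-component substreams
(addresses = 1, facilities = 2); the road lattice and timetable are
deterministic functions of the configuration, so adding a component never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GenerationError
from .types import (
    AreaTypology,
    CityConfig,
    RoadNetwork,
    TransitFeed,
    TYPOLOGY_LABELS,
    TIER_BY_SERVICE,
    validate_addresses,
    validate_facilities,
)

_ADDRESS_STREAM = 1
_FACILITY_STREAM = 2


# ---------------------------------------------------------------------------
# Road lattice

@dataclass(frozen=True)
class _Lattice:
    """Polar-grid geometry shared by the road and transit builders.

    ``n_spokes`` counts every radial line (major and infill); roughly
    eight of them, evenly spaced, are major spokes carrying the
    freeway / arterial hierarchy.
    """

    radii: Tuple[float, ...]          # orbital ring-road radii, ascending
    n_spokes: int

    def node_id(self, i_radius: int, j_spoke: int) -> int:
        # node 0 is the city centre; i_radius counts from 1
        return 1 + (i_radius - 1) * self.n_spokes + (j_spoke % self.n_spokes)

    def angle(self, j_spoke: int) -> float:
        return 2.0 * math.pi * j_spoke / self.n_spokes

    @property
    def major_every(self) -> int:
        return max(1, round(self.n_spokes / 8))

    def spoke_class(self, j_spoke: int) -> str:
        step = self.major_every
        if j_spoke % step == 0:
            return "freeway" if (j_spoke // step) % 2 == 0 else "arterial"
        # infill radials alternate collector/local block-wise between majors
        return "collector" if (j_spoke // step) % 2 == 0 else "local"

    def major_spokes(self, road_class: str = "") -> List[int]:
        return [
            j for j in range(0, self.n_spokes, self.major_every)
            if not road_class or self.spoke_class(j) == road_class
        ]


def _build_lattice(config: CityConfig) -> _Lattice:
    s = config.road_grid_spacing_m
    n_r = int(math.floor(config.ring_radii_m[-1] / s + 1e-9))
    if n_r < 1:
        raise GenerationError("road_grid_spacing_m exceeds the study radius")
    return _Lattice(tuple(s * (i + 1) for i in range(n_r)), config.n_spokes)


def build_road_network(config: CityConfig) -> RoadNetwork:
    """Deterministic polar-lattice road network for the configuration.

    Radial lines alternate freeway/arterial on the major spokes and
    collector/local on the infill ones; every orbital ring road is
    sub-arterial.
    """
    config.validate()
    lat = _build_lattice(config)
    nodes: List[Tuple[int, float, float]] = [(0, 0.0, 0.0)]
    for i, r in enumerate(lat.radii, start=1):
        for j in range(lat.n_spokes):
            th = lat.angle(j)
            nodes.append((lat.node_id(i, j), r * math.cos(th), r * math.sin(th)))

    edges: List[Tuple[int, int, float, str]] = []
    for j in range(lat.n_spokes):
        cls = lat.spoke_class(j)
        prev_id, prev_r = 0, 0.0
        for i, r in enumerate(lat.radii, start=1):
            edges.append((prev_id, lat.node_id(i, j), r - prev_r, cls))
            prev_id, prev_r = lat.node_id(i, j), r
    for i, r in enumerate(lat.radii, start=1):
        arc = r * 2.0 * math.pi / lat.n_spokes  # ring roads follow the circle
        for j in range(lat.n_spokes):
            edges.append((lat.node_id(i, j), lat.node_id(i, j + 1), arc, "sub_arterial"))

    network = RoadNetwork(
        nodes=pd.DataFrame(nodes, columns=["node_id", "x", "y"]),
        edges=pd.DataFrame(edges, columns=["from_node", "to_node", "length_m", "road_class"]),
    )
    return network.validate()


# ---------------------------------------------------------------------------
# Random point sets

def _uniform_in_annulus(
    rng: np.random.Generator, n: int, lo: float, hi: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform-over-area sampling inside an annulus lo <= r < hi."""
    r = np.sqrt(rng.uniform(lo**2, hi**2, size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return r * np.cos(theta), r * np.sin(theta)


def sample_addresses(
    typologies: Sequence[AreaTypology], n_per_typology: int, seed: int
) -> pd.DataFrame:
    """Random residential address points, uniform over each annulus.

    Returns a DataFrame (address_id, x, y, typology) with exactly
    ``n_per_typology`` points per typology, deterministic in ``seed``.
    """
    if n_per_typology < 1:
        raise GenerationError("n_per_typology must be >= 1")
    rng = np.random.default_rng([seed, _ADDRESS_STREAM])
    frames = []
    offset = 0
    for t in typologies:
        lo, hi = t.ring_bounds
        if hi <= lo:
            raise GenerationError(f"typology ring {t.label!r} is empty (bounds {lo}, {hi})")
        x, y = _uniform_in_annulus(rng, n_per_typology, lo, hi)
        frames.append(
            pd.DataFrame(
                {
                    "address_id": np.arange(offset, offset + n_per_typology),
                    "x": x,
                    "y": y,
                    "typology": t.label,
                }
            )
        )
        offset += n_per_typology
    return validate_addresses(pd.concat(frames, ignore_index=True))


def generate_facilities(config: CityConfig) -> pd.DataFrame:
    """Facility points per service type and ring, uniform within each ring."""
    config.validate()
    rng = np.random.default_rng([config.seed, _FACILITY_STREAM])
    typologies = config.typologies
    rows = []
    for stype in sorted(config.facility_counts):
        counts = config.facility_counts[stype]
        k = 0
        for t, count in zip(typologies, counts):
            lo, hi = t.ring_bounds
            x, y = _uniform_in_annulus(rng, int(count), lo, hi)
            for xi, yi in zip(x, y):
                rows.append((f"{stype}_{k:04d}", xi, yi, stype, TIER_BY_SERVICE[stype]))
                k += 1
    df = pd.DataFrame(rows, columns=["facility_id", "x", "y", "service_type", "tier"])
    return validate_facilities(df)


# ---------------------------------------------------------------------------
# Transit feed

def _route_headway_s(config: CityConfig, route_base: str, kind_key: str) -> float:
    """Headway in seconds; a route-specific key overrides the kind default."""
    headways = config.transit_headway_min
    minutes = headways.get(route_base, headways[kind_key])
    return float(minutes) * 60.0


def _trip_departures(start_s: int, end_s: int, headway_s: float) -> List[int]:
    """Departure instants start, start+h, ... strictly before the window end."""
    n = int(math.floor((end_s - start_s) / headway_s - 1e-9)) + 1
    n = max(n, 0)
    deps = [int(round(start_s + k * headway_s)) for k in range(n)]
    return [d for d in deps if d < end_s]


def build_route_trips(
    route_id: str,
    stop_node_ids: Sequence[int],
    leg_times_s: Sequence[int],
    headway_s: float,
    window_s: Tuple[int, int],
    service_id: str = "weekday",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Timetable one one-directional route: trips every headway across the window.

    ``leg_times_s`` are the run times between consecutive stops (each >= 1 s,
    so stop times are strictly increasing).  Returns (trips, stop_times)
    frames in the TransitFeed schema.
    """
    offsets = np.concatenate([[0], np.cumsum(leg_times_s)]).astype(int)
    trips = []
    st_rows = []
    for k, dep0 in enumerate(_trip_departures(window_s[0], window_s[1], headway_s)):
        trip_id = f"{route_id}#{k}"
        trips.append((trip_id, route_id, service_id))
        for seq, (node, off) in enumerate(zip(stop_node_ids, offsets)):
            t = dep0 + int(off)
            st_rows.append((trip_id, seq, f"S{node}", t, t))
    trips_df = pd.DataFrame(trips, columns=["trip_id", "route_id", "service_id"])
    st_df = pd.DataFrame(
        st_rows, columns=["trip_id", "stop_sequence", "stop_id", "arrival_s", "departure_s"]
    )
    return trips_df, st_df


def _leg_times(lengths_m: Sequence[float], speed_kmh: float) -> List[int]:
    mps = speed_kmh / 3.6
    return [max(1, int(round(L / mps))) for L in lengths_m]


def generate_transit_feed(network: RoadNetwork, config: CityConfig) -> TransitFeed:
    """Timetabled train-and-bus feed over the polar lattice.

    Trains run the full length of each freeway spoke (even spokes) in both
    directions; one orbital bus loop (both directions) serves each typology
    annulus at the ring road nearest its radial midpoint.  All services run
    Monday-Friday; stop times are strictly increasing within each trip.
    """
    config.validate()
    if len(network.nodes) == 0:
        raise GenerationError("road network is empty")
    lat = _build_lattice(config)
    radii = np.asarray(lat.radii)

    routes: List[Tuple[str, str]] = []
    all_trips: List[pd.DataFrame] = []
    all_st: List[pd.DataFrame] = []
    used_nodes: set[int] = set()

    def add_line(base: str, mode: str, stops: List[int], lengths: List[float],
                 speed_kmh: float, kind_key: str, loop: bool) -> None:
        headway = _route_headway_s(config, base, kind_key)
        legs = _leg_times(lengths, speed_kmh)
        directions = (
            [(":cw", stops, legs), (":ccw", stops[::-1], legs[::-1])]
            if loop
            else [(":out", stops, legs), (":in", stops[::-1], legs[::-1])]
        )
        for suffix, s_nodes, s_legs in directions:
            rid = base + suffix
            routes.append((rid, mode))
            trips_df, st_df = build_route_trips(
                rid, s_nodes, s_legs, headway, config.service_window_s
            )
            all_trips.append(trips_df)
            all_st.append(st_df)
        used_nodes.update(stops)

    # trains along the freeway spokes, stopping at every ring crossing
    for j in lat.major_spokes("freeway"):
        stops = [0] + [lat.node_id(i, j) for i in range(1, len(radii) + 1)]
        lengths = [radii[0]] + list(np.diff(radii))
        add_line(f"train_{j}", "train", stops, [float(L) for L in lengths],
                 config.train_speed_kmh, "train", loop=False)

    # one orbital bus loop per typology annulus, stopping at major spokes
    majors = lat.major_spokes()
    for t in config.typologies:
        lo, hi = t.ring_bounds
        mid = 0.5 * (lo + hi)
        i = int(np.argmin(np.abs(radii - mid))) + 1
        r = radii[i - 1]
        stops = [lat.node_id(i, j) for j in majors] + [lat.node_id(i, majors[0])]
        angles = [lat.angle(j) for j in majors] + [lat.angle(majors[0]) + 2 * math.pi]
        lengths = [r * (b - a) for a, b in zip(angles[:-1], angles[1:])]
        add_line(f"bus_{t.label}", "bus", stops, lengths,
                 config.bus_speed_kmh, f"bus_{t.label}", loop=True)

    node_xy = network.nodes.set_index("node_id")
    stops_df = pd.DataFrame(
        [
            (f"S{n}", f"S{n}", float(node_xy.loc[n, "x"]), float(node_xy.loc[n, "y"]))
            for n in sorted(used_nodes)
        ],
        columns=["stop_id", "stop_name", "x", "y"],
    )
    calendar = pd.DataFrame(
        [
            {
                "service_id": "weekday",
                **{d: (1 if i < 5 else 0) for i, d in enumerate(
                    ("monday", "tuesday", "wednesday", "thursday", "friday",
                     "saturday", "sunday"))},
            }
        ]
    )
    feed = TransitFeed(
        stops=stops_df,
        routes=pd.DataFrame(routes, columns=["route_id", "mode"]),
        trips=pd.concat(all_trips, ignore_index=True),
        stop_times=pd.concat(all_st, ignore_index=True),
        calendar=calendar,
    )
    return feed.validate()


# ---------------------------------------------------------------------------
# Whole-city generation

def generate_city(
    config: CityConfig,
) -> Tuple[RoadNetwork, TransitFeed, pd.DataFrame, pd.DataFrame, Tuple[AreaTypology, ...]]:
    """Generate a complete, mutually consistent synthetic city.

    Returns (road network, transit feed, facilities, addresses, typologies).
    Identical configurations (including seed) yield identical cities.
    """
    config.validate()
    network = build_road_network(config)
    facilities = generate_facilities(config)
    if config.addresses_per_typology == 0:
        addresses = pd.DataFrame(columns=["address_id", "x", "y", "typology"])
    else:
        addresses = sample_addresses(
            config.typologies, config.addresses_per_typology, config.seed
        )
    feed = generate_transit_feed(network, config)
    return network, feed, facilities, addresses, config.typologies


def facility_density_per_km2(config: CityConfig) -> Dict[str, List[float]]:
    """Configured facility count per km^2 for each service type and ring."""
    out: Dict[str, List[float]] = {}
    for stype, counts in config.facility_counts.items():
        out[stype] = [
            c / (t.area_m2 / 1e6) for c, t in zip(counts, config.typologies)
        ]
    return out
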