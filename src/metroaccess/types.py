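"""Core domain types: area typologies, city configuration, road network,
speed model inputs, transit feed container, and routing parameter bundles.

Coordinates are planar metres on a Cartesian plane centred on the city
centre; the study area is a disc partitioned into five concentric annuli
(the area typologies).  Point sets (facilities, addresses) and tabular
results (OD matrices, summaries) are plain :class:`pandas.DataFrame`
objects with documented column schemas, validated by helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, FeedError

# ---------------------------------------------------------------------------
# Area typologies

TYPOLOGY_LABELS: Tuple[str, ...] = (
    "inner",
    "middle",
    "outer_established",
    "outer_growth",
    "outer_fringe",
)

# Health service taxonomy: primary care needs no referral, secondary
# (specialist) care usually does.
PRIMARY_SERVICES: Tuple[str, ...] = (
    "dietician",
    "gp",
    "optometry",
    "pharmacy",
    "podiatry",
    "physiotherapy",
)
SECONDARY_SERVICES: Tuple[str, ...] = ("diabetic_educator", "endocrinologist")
SERVICE_TYPES: Tuple[str, ...] = PRIMARY_SERVICES + SECONDARY_SERVICES
TIER_BY_SERVICE: Dict[str, str] = {
    **{s: "primary" for s in PRIMARY_SERVICES},
    **{s: "secondary" for s in SECONDARY_SERVICES},
}


@dataclass(frozen=True)
class AreaTypology:
    """One concentric annulus of the study disc.

    ``ring_bounds`` are the inner (inclusive) and outer (exclusive, except
    for the outermost ring) radial distances in metres from the city centre.
    """

    label: str
    ring_bounds: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.label not in TYPOLOGY_LABELS:
            raise ConfigError(f"unknown typology label {self.label!r}")
        lo, hi = self.ring_bounds
        if not (0 <= lo < hi):
            raise ConfigError(f"ring bounds for {self.label!r} must satisfy 0 <= lo < hi")

    @property
    def area_m2(self) -> float:
        lo, hi = self.ring_bounds
        return float(np.pi * (hi**2 - lo**2))


def build_typologies(ring_radii_m: Sequence[float]) -> Tuple[AreaTypology, ...]:
    """Turn five increasing outer radii into the five disjoint annuli."""
    if len(ring_radii_m) != len(TYPOLOGY_LABELS):
        raise ConfigError(f"expected {len(TYPOLOGY_LABELS)} ring radii, got {len(ring_radii_m)}")
    radii = [float(r) for r in ring_radii_m]
    if any(b <= a for a, b in zip([0.0] + radii, radii)):
        raise ConfigError("ring radii must be strictly increasing and positive")
    bounds = zip([0.0] + radii[:-1], radii)
    return tuple(AreaTypology(lab, (lo, hi)) for lab, (lo, hi) in zip(TYPOLOGY_LABELS, bounds))


def typology_of(x: np.ndarray, y: np.ndarray, typologies: Sequence[AreaTypology]) -> np.ndarray:
    """Label each planar point with the annulus containing it.

    Points on a shared boundary belong to the outer ring; points beyond the
    outermost radius get the label ``"outside"`` (buffer facilities).
    """
    r = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    edges = [t.ring_bounds[1] for t in typologies]
    idx = np.searchsorted(edges, r, side="left")
    labels = np.array([t.label for t in typologies] + ["outside"], dtype=object)
    return labels[np.minimum(idx, len(typologies))]


# ---------------------------------------------------------------------------
# City configuration

#: Facilities per service type per ring, inner -> outer fringe.  Densities
#: (count / ring area) decline monotonically outward, most sharply for the
#: referral-based secondary services, mirroring the centralisation gradient
#: of real metropolitan service provision.
DEFAULT_FACILITY_COUNTS: Dict[str, Tuple[int, ...]] = {
    "dietician": (10, 8, 5, 3, 2),
    "gp": (30, 25, 18, 8, 4),
    "optometry": (12, 10, 7, 4, 2),
    "pharmacy": (28, 24, 16, 8, 4),
    "podiatry": (8, 6, 4, 2, 1),
    "physiotherapy": (12, 10, 7, 4, 2),
    "diabetic_educator": (8, 4, 2, 1, 1),
    "endocrinologist": (6, 3, 1, 1, 0),
}

#: Service headways in minutes.  Trains run on the freeway spokes; one
#: orbital bus ring serves each typology annulus, with headways lengthening
#: outward (the transit-coverage gradient of the study area).
DEFAULT_HEADWAYS_MIN: Dict[str, float] = {
    "train": 10.0,
    "bus_inner": 10.0,
    "bus_middle": 15.0,
    "bus_outer_established": 20.0,
    "bus_outer_growth": 30.0,
    "bus_outer_fringe": 40.0,
}


@dataclass
class CityConfig:
    """Parameters of the synthetic metropolitan area.

    Defaults describe a 15 km-radius city with five 3 km-wide annuli and
    a 1 km polar road lattice of 48 radial lines, of which every sixth is
    a major spoke (freeway/arterial); trains run on the freeway spokes
    and one orbital bus route serves each annulus.
    ``addresses_per_typology`` defaults to a small test scale; the full
    study scale of 10,000 per typology is available by configuration.
    """

    seed: int = 0
    addresses_per_typology: int = 200
    ring_radii_m: Tuple[float, ...] = (3000.0, 6000.0, 9000.0, 12000.0, 15000.0)
    facility_counts: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FACILITY_COUNTS)
    )
    road_grid_spacing_m: float = 1000.0
    n_spokes: int = 48
    transit_headway_min: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEADWAYS_MIN)
    )
    service_window_s: Tuple[int, int] = (10 * 3600, 15 * 3600)
    walk_speed_kmh: float = 5.0
    train_speed_kmh: float = 60.0
    bus_speed_kmh: float = 25.0

    def validate(self) -> None:
        if self.addresses_per_typology < 0:
            raise ConfigError("addresses_per_typology must be >= 0")
        build_typologies(self.ring_radii_m)  # raises on bad radii
        for stype, counts in self.facility_counts.items():
            if len(counts) != len(TYPOLOGY_LABELS):
                raise ConfigError(f"facility_counts[{stype!r}] needs one count per ring")
            if any(c < 0 for c in counts):
                raise ConfigError(f"facility_counts[{stype!r}] has a negative count")
        if self.road_grid_spacing_m <= 0:
            raise ConfigError("road_grid_spacing_m must be > 0")
        if self.n_spokes < 3:
            raise ConfigError("n_spokes must be >= 3")
        if any(h <= 0 for h in self.transit_headway_min.values()):
            raise ConfigError("all transit headways must be > 0")
        lo, hi = self.service_window_s
        if not (0 <= lo < hi):
            raise ConfigError("service window must satisfy 0 <= start < end")
        for name in ("walk_speed_kmh", "train_speed_kmh", "bus_speed_kmh"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def typologies(self) -> Tuple[AreaTypology, ...]:
        return build_typologies(self.ring_radii_m)


# ---------------------------------------------------------------------------
# Road network

ROAD_CLASS_LABELS: Tuple[str, ...] = (
    "freeway",
    "arterial",
    "sub_arterial",
    "collector",
    "local",
)


@dataclass(frozen=True)
class RoadClass:
    """A road-hierarchy class with its sign-posted and measured off-peak speeds.

    ``actual_inner_kmh`` / ``actual_outer_kmh`` are the average observed
    off-peak speeds in inner and outer regions; ``None`` when unmeasured
    (collector and local roads).
    """

    label: str
    sign_posted_kmh: float
    actual_inner_kmh: Optional[float] = None
    actual_outer_kmh: Optional[float] = None


#: The default five-class hierarchy with sign-posted and observed speeds.
DEFAULT_ROAD_CLASSES: Dict[str, RoadClass] = {
    "freeway": RoadClass("freeway", 100.0, 70.0, 80.0),
    "arterial": RoadClass("arterial", 80.0, 32.5, 43.0),
    "sub_arterial": RoadClass("sub_arterial", 60.0, 28.0, 38.0),
    "collector": RoadClass("collector", 50.0),
    "local": RoadClass("local", 40.0),
}

NODE_COLUMNS = ("node_id", "x", "y")
EDGE_COLUMNS = ("from_node", "to_node", "length_m", "road_class")


@dataclass
class RoadNetwork:
    """Undirected planar road graph: a node table and a classed edge table.

    ``nodes``: columns (node_id, x, y); ``edges``: columns
    (from_node, to_node, length_m, road_class).  Every edge is traversable
    in both directions.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def validate(self) -> "RoadNetwork":
        for col in NODE_COLUMNS:
            if col not in self.nodes.columns:
                raise ConfigError(f"road network nodes missing column {col!r}")
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                raise ConfigError(f"road network edges missing column {col!r}")
        ids = set(self.nodes["node_id"])
        dangling = set(self.edges["from_node"]) | set(self.edges["to_node"])
        if not dangling <= ids:
            missing = sorted(dangling - ids)[:5]
            raise ConfigError(f"edge endpoints missing from node table: {missing}")
        if (self.edges["length_m"] <= 0).any():
            raise ConfigError("all edge lengths must be strictly positive")
        bad = set(self.edges["road_class"]) - set(ROAD_CLASS_LABELS)
        if bad:
            raise ConfigError(f"unknown road classes: {sorted(bad)}")
        self.nodes = self.nodes.sort_values("node_id").reset_index(drop=True)
        return self

    def node_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        """Node ids and coordinates in ascending node_id order."""
        n = self.nodes.sort_values("node_id")
        return n["node_id"].to_numpy(), n[["x", "y"]].to_numpy(dtype=float)

    def snap_points(self, x, y) -> np.ndarray:
        """Nearest network node for each point (Euclidean; ties -> lowest id)."""
        ids, xy = self.node_xy()
        pts = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
        # brute force; node counts here are small, and argmin on an
        # id-ordered array breaks distance ties toward the lowest node id
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        return ids[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# Speed model

@dataclass(frozen=True)
class SpeedModel:
    """Estimated off-peak travel speed per road class, km/h.

    The m/s view is derived (v / 3.6); the reporting layer rounds it to
    two decimals.
    """

    estimated_kmh: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.estimated_kmh.values()):
            raise ConfigError("all estimated speeds must be > 0")

    @property
    def estimated_mps(self) -> Dict[str, float]:
        return {k: v / 3.6 for k, v in self.estimated_kmh.items()}


# ---------------------------------------------------------------------------
# Transit

GTFS_FILES = ("stops.txt", "routes.txt", "trips.txt", "stop_times.txt", "calendar.txt")
WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")

#: GTFS route_type -> coarse mode used in this analysis.
ROUTE_TYPE_TO_MODE = {0: "tram", 1: "train", 2: "train", 3: "bus"}
MODE_TO_ROUTE_TYPE = {"tram": 0, "train": 2, "bus": 3}


@dataclass
class TransitFeed:
    """In-memory minimal GTFS feed.

    ``stops``: (stop_id, stop_name, x, y); ``routes``: (route_id, mode);
    ``trips``: (trip_id, route_id, service_id); ``stop_times``:
    (trip_id, stop_sequence, stop_id, arrival_s, departure_s) with
    seconds-after-midnight times; ``calendar``: (service_id, monday ...
    sunday) 0/1 flags.
    """

    stops: pd.DataFrame
    routes: pd.DataFrame
    trips: pd.DataFrame
    stop_times: pd.DataFrame
    calendar: pd.DataFrame

    def validate(self) -> "TransitFeed":
        stop_ids = set(self.stops["stop_id"])
        route_ids = set(self.routes["route_id"])
        trip_ids = set(self.trips["trip_id"])
        service_ids = set(self.calendar["service_id"])
        if not set(self.trips["route_id"]) <= route_ids:
            raise FeedError("trips.txt references a route_id absent from routes.txt")
        if not set(self.trips["service_id"]) <= service_ids:
            raise FeedError("trips.txt references a service_id absent from calendar.txt")
        if not set(self.stop_times["trip_id"]) <= trip_ids:
            raise FeedError("stop_times.txt references a trip_id absent from trips.txt")
        if not set(self.stop_times["stop_id"]) <= stop_ids:
            raise FeedError("stop_times.txt references a stop_id absent from stops.txt")
        st = self.stop_times.sort_values(["trip_id", "stop_sequence"])
        if (st["departure_s"] < st["arrival_s"]).any():
            bad = st.loc[st["departure_s"] < st["arrival_s"], "trip_id"].iloc[0]
            raise FeedError(f"stop_times.txt: departure before arrival in trip {bad!r}")
        for trip_id, grp in st.groupby("trip_id", sort=False):
            arr = grp["arrival_s"].to_numpy()
            dep = grp["departure_s"].to_numpy()
            if len(arr) > 1 and (arr[1:] <= dep[:-1]).any():
                raise FeedError(
                    f"stop_times.txt: non-increasing times along trip {trip_id!r}"
                )
        return self

    def trips_active_on(self, weekday: str) -> pd.DataFrame:
        """Trips whose service runs on the given weekday name."""
        day = weekday.lower()
        if day not in WEEKDAYS:
            raise FeedError(f"unknown weekday {day!r}")
        active = set(self.calendar.loc[self.calendar[day] == 1, "service_id"])
        return self.trips[self.trips["service_id"].isin(active)]


@dataclass(frozen=True)
class WalkParams:
    """Walking-leg parameters for multimodal journeys."""

    walk_speed_kmh: float = 5.0
    max_access_walk_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.walk_speed_kmh <= 0:
            raise ConfigError("walk_speed_kmh must be > 0")
        if self.max_access_walk_m is not None and self.max_access_walk_m < 0:
            raise ConfigError("max_access_walk_m must be >= 0 or None")

    @property
    def walk_speed_mps(self) -> float:
        return self.walk_speed_kmh / 3.6


@dataclass(frozen=True)
class DepartureSpec:
    """Fixed departure instant for the public-transport OD matrix
    (default: Wednesday noon, an off-peak weekday time)."""

    weekday: str = "wednesday"
    depart_s: int = 12 * 3600

    def __post_init__(self) -> None:
        if self.weekday.lower() not in WEEKDAYS:
            raise ConfigError(f"unknown weekday {self.weekday!r}")
        if not (0 <= self.depart_s < 86400):
            raise ConfigError("depart_s must lie in [0, 86400)")


# ---------------------------------------------------------------------------
# Point-set and result schemas (plain DataFrames)

FACILITY_COLUMNS = ("facility_id", "x", "y", "service_type", "tier")
ADDRESS_COLUMNS = ("address_id", "x", "y", "typology")
OD_COLUMNS = ("address_id", "typology", "service_type", "mode", "minutes")
SUMMARY_COLUMNS = (
    "typology", "service_type", "mode",
    "n", "median", "q1", "q3", "min", "max", "n_unreachable",
)


def validate_facilities(df: pd.DataFrame) -> pd.DataFrame:
    """Check the facility-set schema and the service-type/tier mapping."""
    for col in FACILITY_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"facility set missing column {col!r}")
    bad = set(df["service_type"]) - set(SERVICE_TYPES)
    if bad:
        raise ConfigError(f"unknown service types: {sorted(bad)}")
    mismatch = df[df["tier"] != df["service_type"].map(TIER_BY_SERVICE)]
    if len(mismatch):
        raise ConfigError(
            f"tier/service mismatch for facilities {mismatch['facility_id'].tolist()[:5]}"
        )
    return df


def validate_addresses(df: pd.DataFrame) -> pd.DataFrame:
    for col in ADDRESS_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"address sample missing column {col!r}")
    bad = set(df["typology"]) - set(TYPOLOGY_LABELS)
    if bad:
        raise ConfigError(f"unknown typologies: {sorted(bad)}")
    return df
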