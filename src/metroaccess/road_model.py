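"""Road-hierarchy speed estimation and private-vehicle travel-time routing.

Off-peak driving speeds are estimated per road class from sign-posted
limits and observed average speeds: where inner- and outer-region
measurements exist the estimate is their arithmetic mean; where no
measurements exist (collector, local) the estimate is half the sign-posted
limit — the ratio observed on the measured classes.  Travel time on an
edge is length / estimated speed; origin-destination times are
shortest-path times over the undirected classed network, with origins and
destinations attached to their nearest network node.  Door-to-vehicle
time, congestion, signals and turn penalties are not modelled.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SpeedModelError
from .types import (
    DEFAULT_ROAD_CLASSES,
    RoadClass,
    RoadNetwork,
    SpeedModel,
    validate_addresses,
    validate_facilities,
)

logger = logging.getLogger(__name__)

UNREACHABLE = math.inf  # in-memory sentinel for cells with no path


def estimate_class_speed(road_class: RoadClass) -> float:
    """Estimated off-peak speed (km/h) for one road class.

    Mean of the inner and outer observed speeds when both are known,
    otherwise half the sign-posted limit.  A single known observation is
    treated as insufficient and falls back to the half-rule.
    """
    if road_class.sign_posted_kmh <= 0:
        raise SpeedModelError(
            f"sign-posted speed must be > 0 for class {road_class.label!r}"
        )
    inner, outer = road_class.actual_inner_kmh, road_class.actual_outer_kmh
    if inner is not None and outer is not None:
        return (inner + outer) / 2.0
    return road_class.sign_posted_kmh / 2.0


def kmh_to_mps(v_kmh: float) -> float:
    """km/h to m/s (divide by 3.6); reporting rounds to 2 decimals."""
    if v_kmh < 0:
        raise SpeedModelError("speed must be non-negative")
    return v_kmh / 3.6


def default_speed_model(
    road_classes: Optional[Mapping[str, RoadClass]] = None,
    overrides: Optional[Mapping[str, float]] = None,
) -> SpeedModel:
    """The estimated speed model over the default five-class hierarchy.

    ``overrides`` replaces individual class estimates (km/h) after
    estimation, e.g. from a configuration file.
    """
    classes = dict(road_classes or DEFAULT_ROAD_CLASSES)
    est = {label: estimate_class_speed(rc) for label, rc in classes.items()}
    if overrides:
        est.update({k: float(v) for k, v in overrides.items()})
    return SpeedModel(est)


def edge_travel_time(length_m: float, road_class: str, model: SpeedModel) -> float:
    """Travel time in minutes for one edge under the speed model."""
    if road_class not in model.estimated_kmh:
        raise SpeedModelError(f"no estimated speed for road class {road_class!r}")
    speed_m_per_min = model.estimated_kmh[road_class] * 1000.0 / 60.0
    return length_m / speed_m_per_min


def travel_time_graph(network: RoadNetwork, model: SpeedModel) -> nx.Graph:
    """Undirected graph weighted by per-edge driving minutes."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes["node_id"])
    for row in network.edges.itertuples(index=False):
        t = edge_travel_time(row.length_m, row.road_class, model)
        # parallel edges collapse to the fastest one
        if g.has_edge(row.from_node, row.to_node):
            t = min(t, g[row.from_node][row.to_node]["minutes"])
        g.add_edge(row.from_node, row.to_node, minutes=t)
    return g


def nearest_type_times(
    graph: nx.Graph,
    facility_nodes_by_type: Mapping[str, Iterable[int]],
) -> Dict[str, Dict[int, float]]:
    """Minutes from every graph node to its nearest facility of each type.

    One multi-source Dijkstra per service type; on an undirected network
    time(node -> facility) equals time(facility -> node).  Nodes with no
    path to any facility of a type are absent from that type's map.
    """
    out: Dict[str, Dict[int, float]] = {}
    for stype, nodes in facility_nodes_by_type.items():
        sources = set(nodes)
        if not sources:
            out[stype] = {}
            continue
        out[stype] = nx.multi_source_dijkstra_path_length(
            graph, sources, weight="minutes"
        )
    return out


def od_times_from_nearest(
    origins: pd.DataFrame,
    origin_nodes: np.ndarray,
    nearest: Mapping[str, Mapping[int, float]],
    mode: str,
) -> pd.DataFrame:
    """Assemble the OD table (address_id, typology, service_type, mode, minutes).

    Unreachable cells carry +inf and are counted in a warning, never dropped:
    the output always has exactly len(origins) x len(service types) rows.
    """
    frames = []
    for stype in sorted(nearest):
        dist = nearest[stype]
        minutes = np.array(
            [dist.get(n, UNREACHABLE) for n in origin_nodes], dtype=float
        )
        frames.append(
            pd.DataFrame(
                {
                    "address_id": origins["address_id"].to_numpy(),
                    "typology": origins["typology"].to_numpy(),
                    "service_type": stype,
                    "mode": mode,
                    "minutes": minutes,
                }
            )
        )
    od = pd.concat(frames, ignore_index=True)
    n_unreachable = int(np.isinf(od["minutes"]).sum())
    if n_unreachable:
        logger.warning("%s OD matrix: %d unreachable cells", mode, n_unreachable)
    return od


def private_od_times(
    network: RoadNetwork,
    model: SpeedModel,
    origins: pd.DataFrame,
    destinations: pd.DataFrame,
) -> pd.DataFrame:
    """Private-vehicle minutes from every address to its nearest facility
    of each service type.

    Origins and facilities snap to their nearest network node (Euclidean,
    ties to the lowest node id).  Returns the OD table with mode
    ``"private"``; unreachable cells are +inf.
    """
    validate_addresses(origins)
    validate_facilities(destinations)
    graph = travel_time_graph(network, model)
    fac_nodes = destinations.assign(
        node=network.snap_points(destinations["x"], destinations["y"])
    )
    by_type = {
        stype: grp["node"].tolist()
        for stype, grp in fac_nodes.groupby("service_type", sort=True)
    }
    origin_nodes = network.snap_points(origins["x"], origins["y"])
    nearest = nearest_type_times(graph, by_type)
    logger.info(
        "private routing: %d origins, %d facility types, %d nodes",
        len(origins), len(by_type), graph.number_of_nodes(),
    )
    return od_times_from_nearest(origins, origin_nodes, nearest, "private")
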