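"""File formats: GeoJSON point sets, road-network CSVs, GTFS text files,
and CSV result tables.

All coordinates are planar metres; GeoJSON Point coordinates and GTFS
stop_lon/stop_lat carry (x, y) directly.  Round trips are lossless to
1e-6 m for coordinates and 1e-9 min for travel times (floats are written
at full repr precision).  Unreachable OD cells are written as empty
minutes cells (with a logged count) and read back as +inf.
"""

from __future__ import annotations

import json
import logging
import math
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .transit_model import format_gtfs_time
from .types import (
    MODE_TO_ROUTE_TYPE,
    OD_COLUMNS,
    RoadNetwork,
    TransitFeed,
    WEEKDAYS,
    validate_addresses,
    validate_facilities,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GeoJSON point sets

def write_points(
    df: pd.DataFrame, path: str, id_column: str, property_columns: Sequence[str]
) -> None:
    """Write a point table as a GeoJSON FeatureCollection."""
    features = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        features.append(
            {
                "type": "Feature",
                "id": rec[id_column],
                "geometry": {"type": "Point", "coordinates": [rec["x"], rec["y"]]},
                "properties": {c: rec[c] for c in property_columns},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_points(
    path: str, id_column: str, property_columns: Sequence[str]
) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection of Points back into a table.

    Missing geometry or a missing required property raises
    :class:`ParseError` naming the feature index.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point" or "coordinates" not in geom:
            raise ParseError(f"{path}: feature {i} lacks a Point geometry")
        props = feat.get("properties") or {}
        missing = [c for c in property_columns if c not in props]
        if missing:
            raise ParseError(
                f"{path}: feature {i} missing propert{'y' if len(missing)==1 else 'ies'} "
                f"{missing}"
            )
        x, y = geom["coordinates"]
        rows.append({id_column: feat.get("id", i), "x": float(x), "y": float(y),
                     **{c: props[c] for c in property_columns}})
    return pd.DataFrame(rows, columns=[id_column, "x", "y", *property_columns])


def write_facilities(df: pd.DataFrame, path: str) -> None:
    write_points(validate_facilities(df), path, "facility_id", ["service_type", "tier"])


def read_facilities(path: str) -> pd.DataFrame:
    return validate_facilities(
        read_points(path, "facility_id", ["service_type", "tier"])
    )


def write_addresses(df: pd.DataFrame, path: str) -> None:
    df = df.copy()
    df["address_id"] = df["address_id"].astype(int)
    write_points(validate_addresses(df), path, "address_id", ["typology"])


def read_addresses(path: str) -> pd.DataFrame:
    df = read_points(path, "address_id", ["typology"])
    df["address_id"] = df["address_id"].astype(int)
    return validate_addresses(df)


# ---------------------------------------------------------------------------
# Road network CSVs

def write_network(network: RoadNetwork, directory: str) -> None:
    """Write nodes.csv (id,x,y) and edges.csv (from,to,length_m,class)."""
    os.makedirs(directory, exist_ok=True)
    network.nodes.to_csv(os.path.join(directory, "nodes.csv"), index=False)
    network.edges.to_csv(os.path.join(directory, "edges.csv"), index=False)


def read_network(directory: str) -> RoadNetwork:
    nodes_path = os.path.join(directory, "nodes.csv")
    edges_path = os.path.join(directory, "edges.csv")
    for p in (nodes_path, edges_path):
        if not os.path.exists(p):
            raise ParseError(f"missing network file: {p}")
    try:
        nodes = pd.read_csv(nodes_path, dtype={"node_id": int, "x": float, "y": float})
        edges = pd.read_csv(
            edges_path,
            dtype={"from_node": int, "to_node": int, "length_m": float, "road_class": str},
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"malformed network CSV in {directory}: {exc}") from exc
    return RoadNetwork(nodes=nodes, edges=edges).validate()


# ---------------------------------------------------------------------------
# GTFS

def write_gtfs(feed: TransitFeed, directory: str) -> None:
    """Write the feed as standard GTFS text files (planar metres in
    stop_lon/stop_lat; times as HH:MM:SS, hours may exceed 24)."""
    os.makedirs(directory, exist_ok=True)
    stops = pd.DataFrame(
        {
            "stop_id": feed.stops["stop_id"],
            "stop_name": feed.stops["stop_name"],
            "stop_lat": feed.stops["y"],
            "stop_lon": feed.stops["x"],
        }
    )
    stops.to_csv(os.path.join(directory, "stops.txt"), index=False)
    routes = pd.DataFrame(
        {
            "route_id": feed.routes["route_id"],
            "route_short_name": feed.routes["route_id"],
            "route_type": feed.routes["mode"].map(lambda m: MODE_TO_ROUTE_TYPE.get(m, 3)),
        }
    )
    routes.to_csv(os.path.join(directory, "routes.txt"), index=False)
    feed.trips[["route_id", "service_id", "trip_id"]].to_csv(
        os.path.join(directory, "trips.txt"), index=False
    )
    st = feed.stop_times.sort_values(["trip_id", "stop_sequence"])
    pd.DataFrame(
        {
            "trip_id": st["trip_id"],
            "arrival_time": st["arrival_s"].map(format_gtfs_time),
            "departure_time": st["departure_s"].map(format_gtfs_time),
            "stop_id": st["stop_id"],
            "stop_sequence": st["stop_sequence"],
        }
    ).to_csv(os.path.join(directory, "stop_times.txt"), index=False)
    cal = feed.calendar.copy()
    cal["start_date"] = "20150101"
    cal["end_date"] = "20251231"
    cal[["service_id", *WEEKDAYS, "start_date", "end_date"]].to_csv(
        os.path.join(directory, "calendar.txt"), index=False
    )


# ---------------------------------------------------------------------------
# Result tables

def write_od(od: pd.DataFrame, path: str) -> None:
    """OD CSV (address_id,typology,service_type,mode,minutes); unreachable
    cells become empty minutes cells and are counted in a warning."""
    out = od[list(OD_COLUMNS)].copy()
    n_unreachable = int(np.isinf(out["minutes"]).sum())
    if n_unreachable:
        logger.warning("writing %s: %d unreachable cells left empty", path, n_unreachable)
    out["minutes"] = out["minutes"].map(
        lambda v: "" if math.isinf(v) else repr(float(v))
    )
    out.to_csv(path, index=False)


def read_od(path: str) -> pd.DataFrame:
    """Read an OD CSV; empty minutes cells become +inf, anything
    non-numeric raises :class:`ParseError` naming the row."""
    df = pd.read_csv(path, dtype={"minutes": str}, keep_default_na=False)
    missing = [c for c in OD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    minutes = []
    for i, text in enumerate(df["minutes"]):
        if text == "":
            minutes.append(math.inf)
            continue
        try:
            minutes.append(float(text))
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-numeric minutes {text!r} at data row {i + 1}"
            ) from exc
    df["minutes"] = minutes
    df["address_id"] = df["address_id"].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
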