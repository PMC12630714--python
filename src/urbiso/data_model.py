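"""Domain tables, readers/writers and validation for cities, networks and events.

Tables are plain :class:`pandas.DataFrame` objects with fixed column schemas
(UTF-8 CSV, ``.`` decimal separator); the road network is a small dataclass
bundling a node table and an edge table.  All coordinates are WGS84 decimal
degrees, distances are kilometres and travel times are hours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: the six event categories, in canonical order
CATEGORIES = (
    "battle",
    "violence_against_civilians",
    "explosion_remote",
    "strategic_development",
    "riot",
    "protest",
)

#: the four categories entering the default casualty totals
CASUALTY_CATEGORIES = (
    "battle",
    "violence_against_civilians",
    "explosion_remote",
    "strategic_development",
)

#: mapping from ACLED export ``event_type`` strings to canonical categories
ACLED_EVENT_TYPES = {
    "battles": "battle",
    "violence against civilians": "violence_against_civilians",
    "explosions/remote violence": "explosion_remote",
    "strategic developments": "strategic_development",
    "riots": "riot",
    "protests": "protest",
}

CITY_COLUMNS = ["city_id", "name", "lon", "lat", "country", "population"]
NODE_COLUMNS = ["node_id", "kind", "lon", "lat", "country", "city_ref"]
EDGE_COLUMNS = ["from_node", "to_node", "travel_time_h", "crosses_border"]
EVENT_COLUMNS = ["event_id", "date", "category", "lon", "lat", "fatalities"]

NODE_KINDS = ("city", "junction")


@dataclass
class UrbanNetwork:
    """A road network: city/junction nodes joined by undirected timed edges."""

    nodes: pd.DataFrame
    edges: pd.DataFrame

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def city_nodes(self) -> pd.DataFrame:
        """Return the subset of nodes that represent cities."""
        return self.nodes[self.nodes["kind"] == "city"]


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _check_coords(df: pd.DataFrame, what: str) -> None:
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    if bad.any():
        raise ValidationError(
            f"{what}: {int(bad.sum())} row(s) with coordinates outside "
            "lon [-180, 180] / lat [-90, 90]"
        )


def validate_cities(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a city table in place and return it with typed columns."""
    _require_columns(df, CITY_COLUMNS, "cities")
    df = df.copy()
    if df["city_id"].duplicated().any():
        dupes = df.loc[df["city_id"].duplicated(), "city_id"].tolist()
        raise ValidationError(f"duplicate city_id values: {dupes[:5]}")
    _check_coords(df, "cities")
    pop = pd.to_numeric(df["population"], errors="coerce")
    if pop.isna().any() or (pop < 1).any() or (pop != pop.round()).any():
        raise ValidationError("cities: population must be an integer >= 1")
    df["city_id"] = df["city_id"].astype(str)
    df["country"] = df["country"].astype(str)
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)
    df["population"] = pop.astype(np.int64)
    return df[CITY_COLUMNS]


def validate_network(nodes: pd.DataFrame, edges: pd.DataFrame,
                     cities: pd.DataFrame | None = None) -> UrbanNetwork:
    """Validate node and edge tables and derive ``crosses_border`` if absent."""
    _require_columns(nodes, NODE_COLUMNS[:5], "nodes")
    _require_columns(edges, EDGE_COLUMNS[:3], "edges")
    nodes = nodes.copy()
    edges = edges.copy()
    if "city_ref" not in nodes.columns:
        nodes["city_ref"] = ""
    nodes["node_id"] = nodes["node_id"].astype(str)
    nodes["city_ref"] = nodes["city_ref"].fillna("").astype(str)
    if nodes["node_id"].duplicated().any():
        raise ValidationError("nodes: duplicate node_id values")
    bad_kind = ~nodes["kind"].isin(NODE_KINDS)
    if bad_kind.any():
        raise ValidationError(
            f"nodes: unknown kind value(s) {sorted(nodes.loc[bad_kind, 'kind'].unique())}"
        )
    _check_coords(nodes, "nodes")
    no_ref = (nodes["kind"] == "city") & (nodes["city_ref"] == "")
    if no_ref.any():
        raise ValidationError(
            f"nodes: city nodes without city_ref: {nodes.loc[no_ref, 'node_id'].tolist()[:5]}"
        )
    has_ref = (nodes["kind"] == "junction") & (nodes["city_ref"] != "")
    if has_ref.any():
        raise ValidationError("nodes: junction nodes must not carry a city_ref")
    if cities is not None:
        known = set(cities["city_id"].astype(str))
        refs = set(nodes.loc[nodes["kind"] == "city", "city_ref"])
        unresolved = refs - known
        if unresolved:
            raise ReferentialError(f"nodes: city_ref(s) not in city table: {sorted(unresolved)[:5]}")

    edges["from_node"] = edges["from_node"].astype(str)
    edges["to_node"] = edges["to_node"].astype(str)
    node_ids = set(nodes["node_id"])
    for col in ("from_node", "to_node"):
        dangling = ~edges[col].isin(node_ids)
        if dangling.any():
            row = edges.loc[dangling].iloc[0]
            raise ReferentialError(
                f"edge {row['from_node']}->{row['to_node']}: endpoint "
                f"{row[col]!r} is not a known node"
            )
    tt = pd.to_numeric(edges["travel_time_h"], errors="coerce")
    if tt.isna().any() or (tt <= 0).any() or not np.isfinite(tt).all():
        raise ValidationError("edges: travel_time_h must be finite and > 0")
    edges["travel_time_h"] = tt.astype(float)
    if (edges["from_node"] == edges["to_node"]).any():
        raise ValidationError("edges: self-loops are not allowed")

    country = nodes.set_index("node_id")["country"]
    derived = (
        country.loc[edges["from_node"]].to_numpy()
        != country.loc[edges["to_node"]].to_numpy()
    )
    if "crosses_border" not in edges.columns:
        edges["crosses_border"] = derived
    else:
        filled = edges["crosses_border"]
        if filled.dtype == object:
            filled = filled.map({"True": True, "False": False, True: True, False: False})
        mask = filled.isna()
        edges["crosses_border"] = np.where(mask, derived, filled).astype(bool)
    return UrbanNetwork(nodes=nodes[NODE_COLUMNS], edges=edges[EDGE_COLUMNS])


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table, rejecting (and counting) malformed rows.

    Rows with an unknown category, out-of-range coordinates, unparseable
    dates or negative fatalities are dropped; the count of rejected rows is
    logged and stored in ``df.attrs['n_rejected']``.  Duplicate event ids
    raise, since silently keeping either copy would corrupt aggregates.
    """
    _require_columns(df, EVENT_COLUMNS, "events")
    df = df.copy()
    df["event_id"] = df["event_id"].astype(str)
    if df["event_id"].duplicated().any():
        raise ValidationError("events: duplicate event_id values")
    n_input = len(df)
    reasons: dict[str, int] = {}

    date = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad_date = date.isna()
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_coord = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    fat = pd.to_numeric(df["fatalities"], errors="coerce")
    bad_fat = fat.isna() | (fat < 0) | (fat != fat.round())
    bad_cat = ~df["category"].isin(CATEGORIES)
    for name, mask in [("date", bad_date), ("coordinates", bad_coord),
                       ("fatalities", bad_fat), ("category", bad_cat)]:
        if mask.any():
            reasons[name] = int(mask.sum())
    keep = ~(bad_date | bad_coord | bad_fat | bad_cat)
    out = df.loc[keep, EVENT_COLUMNS].copy()
    out["date"] = date[keep].dt.normalize()
    out["lon"] = lon[keep].astype(float)
    out["lat"] = lat[keep].astype(float)
    out["fatalities"] = fat[keep].astype(np.int64)
    out = out.reset_index(drop=True)
    n_rejected = n_input - len(out)
    if n_rejected:
        logger.warning("events: rejected %d/%d rows (%s)", n_rejected, n_input,
                       ", ".join(f"{k}: {v}" for k, v in reasons.items()))
    out.attrs["n_rejected"] = n_rejected
    out.attrs["rejection_reasons"] = reasons
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_geojson_points(path: str | Path, what: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{what}: GeoJSON must be a FeatureCollection")
    rows = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError(f"{what}: only Point features are supported")
        props = dict(feat.get("properties") or {})
        props["lon"], props["lat"] = geom["coordinates"][:2]
        rows.append(props)
    return pd.DataFrame(rows)


def read_cities(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read and validate a city table from CSV or GeoJSON points."""
    if format == "csv":
        df = pd.read_csv(path, dtype={"city_id": str, "country": str}, comment="#")
    elif format == "geojson":
        df = _read_geojson_points(path, "cities")
    else:
        raise ValueError(f"unknown format {format!r}")
    return validate_cities(df)


def write_cities(cities: pd.DataFrame, path: str | Path) -> None:
    cities[CITY_COLUMNS].to_csv(path, index=False)


def read_network(nodes_path: str | Path, edges_path: str | Path,
                 cities: pd.DataFrame | None = None) -> UrbanNetwork:
    """Read and validate node + edge CSVs into an :class:`UrbanNetwork`."""
    nodes = pd.read_csv(nodes_path, comment="#",
                        dtype={"node_id": str, "country": str, "city_ref": str})
    edges = pd.read_csv(edges_path, comment="#",
                        dtype={"from_node": str, "to_node": str})
    return validate_network(nodes, edges, cities=cities)


def write_network(network: UrbanNetwork, nodes_path: str | Path,
                  edges_path: str | Path) -> None:
    network.nodes.to_csv(nodes_path, index=False)
    network.edges.to_csv(edges_path, index=False)


def read_events(path: str | Path, dialect: str = "native",
                format: str = "csv") -> pd.DataFrame:
    """Read events from a native CSV/GeoJSON or an ACLED-style export.

    The ``acled`` dialect maps the standard export columns
    ``event_date/event_type/latitude/longitude/fatalities`` onto the native
    schema; rows whose ``event_type`` is not one of the six known classes are
    rejected per row and counted, never silently dropped.
    """
    if dialect not in ("native", "acled"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if format == "csv":
        df = pd.read_csv(path, dtype=str, comment="#")
    elif format == "geojson":
        df = _read_geojson_points(path, "events")
    else:
        raise ValueError(f"unknown format {format!r}")
    if dialect == "acled":
        _require_columns(
            df, ["event_date", "event_type", "latitude", "longitude", "fatalities"],
            "acled events")
        out = pd.DataFrame({
            "event_id": df["event_id_cnty"] if "event_id_cnty" in df.columns
            else [f"ev{i}" for i in range(len(df))],
            "date": df["event_date"],
            "category": df["event_type"].str.strip().str.lower().map(ACLED_EVENT_TYPES),
            "lon": df["longitude"],
            "lat": df["latitude"],
            "fatalities": df["fatalities"],
        })
        out["category"] = out["category"].fillna("__unknown__")
        df = out
    return validate_events(df)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events[EVENT_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
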