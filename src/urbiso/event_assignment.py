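"""Nearest-city event assignment under a distance threshold and aggregation.

Each event inside the analysis window (and category filter) is assigned to
its nearest city centre when the great-circle distance is strictly below
``delta_km``; everything else is rural.  Aggregates produce per-city event
counts and casualty totals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data_model import CASUALTY_CATEGORIES, CATEGORIES
from .errors import AnalysisError, ValidationError

EARTH_RADIUS_KM = 6371.0

#: sentinel city id for events beyond delta of every city
RURAL = "RURAL"


@dataclass(frozen=True)
class AssignmentParams:
    delta_km: float = 20.0
    window_start: str | pd.Timestamp = "2000-01-01"
    window_end: str | pd.Timestamp = "2022-10-25"
    categories: tuple[str, ...] = CASUALTY_CATEGORIES

    def __post_init__(self) -> None:
        if self.delta_km <= 0:
            raise ValidationError(f"delta_km must be > 0, got {self.delta_km}")
        start, end = pd.Timestamp(self.window_start), pd.Timestamp(self.window_end)
        if start > end:
            raise ValidationError("window_start must be <= window_end")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        object.__setattr__(self, "window_start", start)
        object.__setattr__(self, "window_end", end)

    def key(self) -> tuple:
        return (self.delta_km, str(self.window_start.date()),
                str(self.window_end.date()), tuple(sorted(self.categories)))


@dataclass
class CityViolenceTable:
    """Per-city violence aggregates for one (delta, window, categories) choice."""

    table: pd.DataFrame  # city_id, population, n_events, casualties_all, casualties_vac
    params: AssignmentParams
    n_rural_events: int = 0
    rural_casualties: int = 0

    @property
    def years(self) -> float:
        span = self.params.window_end - self.params.window_start
        return (span.days + 1) / 365.25


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371.0), vectorised."""
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
            raise ValidationError("coordinates outside lon [-180,180] / lat [-90,90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if d.ndim == 0 else d


def _unit_vectors(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam),
                            np.sin(phi)])


def filter_events(events: pd.DataFrame, params: AssignmentParams) -> pd.DataFrame:
    """Restrict events to the analysis window (inclusive) and category set."""
    date = pd.to_datetime(events["date"])
    keep = (
        (date >= params.window_start)
        & (date <= params.window_end)
        & events["category"].isin(params.categories)
    )
    return events.loc[keep].reset_index(drop=True)


def assign_events(events: pd.DataFrame, cities: pd.DataFrame,
                  params: AssignmentParams) -> pd.DataFrame:
    """Map each in-window, in-category event to its nearest city (or RURAL).

    An event is assigned iff its haversine distance to the nearest city
    centre is strictly below ``delta_km``; exact ties between equidistant
    cities go to the smallest ``city_id``.
    """
    if len(cities) == 0:
        raise AnalysisError("cannot assign events with an empty city table")
    ev = filter_events(events, params)
    clon = cities["lon"].to_numpy(float)
    clat = cities["lat"].to_numpy(float)
    cids = cities["city_id"].to_numpy()
    if len(ev) == 0:
        out = pd.DataFrame(columns=["event_id", "assigned_city", "distance_km"])
        out.attrs["params_key"] = params.key()
        return out

    tree = cKDTree(_unit_vectors(clon, clat))
    k = min(len(cities), 8)
    _, idx = tree.query(_unit_vectors(ev["lon"].to_numpy(float), ev["lat"].to_numpy(float)), k=k)
    idx = np.atleast_2d(idx.T).T  # shape (n_events, k) even when k == 1

    dists = haversine_km(
        ev["lon"].to_numpy(float)[:, None], ev["lat"].to_numpy(float)[:, None],
        clon[idx], clat[idx],
    )
    dists = np.atleast_2d(dists)
    assigned = []
    distance = []
    for row_d, row_i in zip(dists, idx):
        dmin = row_d.min()
        if dmin < params.delta_km:
            ties = row_i[row_d == dmin]
            assigned.append(min(cids[ties]))
        else:
            assigned.append(RURAL)
        distance.append(dmin)
    out = pd.DataFrame({
        "event_id": ev["event_id"].to_numpy(),
        "assigned_city": assigned,
        "distance_km": distance,
    })
    out.attrs["params_key"] = params.key()
    return out


def aggregate_city_violence(assignments: pd.DataFrame, events: pd.DataFrame,
                            cities: pd.DataFrame, params: AssignmentParams,
                            categories_all: tuple[str, ...] = CASUALTY_CATEGORIES,
                            ) -> CityViolenceTable:
    """Per-city event counts and casualty sums from an assignment table.

    ``casualties_all`` sums fatalities over ``categories_all`` (the four
    non-protest categories by default); ``casualties_vac`` sums fatalities of
    violence against civilians only.  Cities without events appear with zeros.
    """
    if assignments.attrs.get("params_key") != params.key():
        raise AnalysisError("assignments were produced under different parameters")
    ev = events.set_index("event_id")
    joined = assignments.join(ev[["category", "fatalities"]], on="event_id")

    urban = joined[joined["assigned_city"] != RURAL]
    in_all = urban["category"].isin(categories_all)
    is_vac = urban["category"] == "violence_against_civilians"
    grp = urban.groupby("assigned_city")
    n_events = grp.size()
    cas_all = urban.loc[in_all].groupby("assigned_city")["fatalities"].sum()
    cas_vac = urban.loc[is_vac].groupby("assigned_city")["fatalities"].sum()

    table = pd.DataFrame({
        "city_id": cities["city_id"].astype(str),
        "population": cities["population"].astype(np.int64),
    })
    for col, series in [("n_events", n_events), ("casualties_all", cas_all),
                        ("casualties_vac", cas_vac)]:
        table[col] = table["city_id"].map(series).fillna(0).astype(np.int64)

    rural = joined[joined["assigned_city"] == RURAL]
    return CityViolenceTable(
        table=table,
        params=params,
        n_rural_events=int(len(rural)),
        rural_casualties=int(rural.loc[rural["category"].isin(categories_all),
                                       "fatalities"].sum()),
    )


def urban_share(assignments: pd.DataFrame, events: pd.DataFrame) -> tuple[float, float]:
    """Fractions of (events, fatalities) in the assignment table that are urban."""
    if len(assignments) == 0:
        raise AnalysisError("urban share undefined for zero events")
    joined = assignments.join(events.set_index("event_id")[["fatalities"]], on="event_id")
    total_fat = joined["fatalities"].sum()
    if total_fat == 0:
        raise AnalysisError("urban casualty share undefined: no fatalities")
    urban = joined["assigned_city"] != RURAL
    return (
        float(urban.mean()),
        float(joined.loc[urban, "fatalities"].sum() / total_fat),
    )


def with_delta(params: AssignmentParams, delta_km: float) -> AssignmentParams:
    """Copy of params at a different distance threshold."""
    return replace(params, delta_km=delta_km)
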