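"""Lethality rates, isolation/centrality impact ratios, and subsampling.

Lethality of a city is its assigned casualties per 100,000 inhabitants
(optionally per year); a group's collective lethality pools casualties and
population before dividing, which equals the population-weighted mean of the
member cities' rates.  The isolation impact theta is the ratio of collective
lethality of high- versus low-isolation cities; the centrality impact
compares the bottom and top centrality quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .event_assignment import (
    RURAL,
    AssignmentParams,
    CityViolenceTable,
    aggregate_city_violence,
    assign_events,
    with_delta,
)

PER = 100_000.0


def city_lethality(casualties: float, population: float, years: float = 1.0) -> float:
    """Casualties per 100,000 inhabitants per year."""
    if population < 1:
        raise AnalysisError(f"population must be >= 1, got {population}")
    if years <= 0:
        raise AnalysisError(f"years must be > 0, got {years}")
    return casualties / (population / PER) / years


def group_lethality(group: set[str] | list[str], table: CityViolenceTable,
                    years: float = 1.0, measure: str = "casualties_all") -> float:
    """Collective lethality of a set of cities: pooled casualties / pooled pop.

    This is *not* the mean of the member cities' rates; it equals their
    population-weighted mean.
    """
    group = set(group)
    if not group:
        raise AnalysisError("group of cities must be nonempty")
    df = table.table
    sub = df[df["city_id"].isin(group)]
    if len(sub) != len(group):
        raise AnalysisError(f"unknown city ids in group: {sorted(group - set(df['city_id']))[:5]}")
    return city_lethality(float(sub[measure].sum()),
                          float(sub["population"].sum()), years)


def _ratio(phi_num: float, phi_den: float) -> float:
    if phi_den == 0:
        if phi_num == 0:
            raise AnalysisError("impact undefined: both groups have zero lethality")
        return float("inf")
    return phi_num / phi_den


def _class_groups(metrics: pd.DataFrame, column: str,
                  labels: tuple[str, str]) -> tuple[set[str], set[str]]:
    groups = []
    for label in labels:
        ids = set(metrics.loc[metrics[column] == label, "city_id"])
        if not ids:
            raise AnalysisError(f"no cities in class {label!r}")
        groups.append(ids)
    return groups[0], groups[1]


def isolation_impact(table: CityViolenceTable, metrics: pd.DataFrame,
                     years: float = 1.0, measure: str = "casualties_all") -> float:
    """theta: lethality of high-isolation cities over low-isolation cities."""
    high, low = _class_groups(metrics, "isolation_class", ("high", "low"))
    return _ratio(group_lethality(high, table, years, measure),
                  group_lethality(low, table, years, measure))


def centrality_impact(table: CityViolenceTable, metrics: pd.DataFrame,
                      years: float = 1.0, measure: str = "casualties_all") -> float:
    """theta^c: lethality of bottom-quartile over top-quartile centrality cities."""
    q1, q4 = _class_groups(metrics, "centrality_class", ("Q1_lowest", "Q4_highest"))
    return _ratio(group_lethality(q1, table, years, measure),
                  group_lethality(q4, table, years, measure))


@dataclass
class LethalityReport:
    per_city: pd.DataFrame  # city_id, population, casualties, lethality
    group_lethality: dict[str, float]
    theta_isolation: float
    theta_centrality: float | None
    delta_km: float
    years: float
    annualised: bool
    measure: str


def lethality_report(table: CityViolenceTable, metrics: pd.DataFrame,
                     measure: str = "casualties_all",
                     annualised: bool = True) -> LethalityReport:
    """Full per-city and per-group lethality summary at one delta."""
    years = table.years if annualised else 1.0
    df = table.table.copy()
    df["lethality"] = [
        city_lethality(c, p, years)
        for c, p in zip(df[measure], df["population"])
    ]
    groups: dict[str, float] = {}
    for label in ("high", "medium", "low"):
        ids = set(metrics.loc[metrics["isolation_class"] == label, "city_id"])
        if ids:
            groups[f"isolation_{label}"] = group_lethality(ids, table, years, measure)
    has_quartiles = metrics["centrality_class"].isin(["Q1_lowest"]).any()
    if has_quartiles:
        for label in ("Q1_lowest", "Q2", "Q3", "Q4_highest"):
            ids = set(metrics.loc[metrics["centrality_class"] == label, "city_id"])
            if ids:
                groups[f"centrality_{label}"] = group_lethality(ids, table, years, measure)
    return LethalityReport(
        per_city=df[["city_id", "population", measure, "lethality"]],
        group_lethality=groups,
        theta_isolation=isolation_impact(table, metrics, years, measure),
        theta_centrality=(centrality_impact(table, metrics, years, measure)
                          if has_quartiles else None),
        delta_km=table.params.delta_km,
        years=years,
        annualised=annualised,
        measure=measure,
    )


@dataclass
class SubsampleDistribution:
    frac: float
    reps: int
    seed: int
    theta_samples: list[float] = field(default_factory=list)
    theta_centrality_samples: list[float] = field(default_factory=list)


def _event_group_arrays(events: pd.DataFrame, cities: pd.DataFrame,
                        metrics: pd.DataFrame, params: AssignmentParams,
                        column: str, labels: tuple[str, str],
                        measure: str) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-event fatality contributions to the two compared groups.

    Event-to-city assignment does not depend on which other events are
    present, so it is computed once on the full filtered event set; event
    subsampling then reduces to subsampling rows of these arrays.
    """
    assignments = assign_events(events, cities, params)
    if len(assignments) < 2:
        raise AnalysisError("need >= 2 in-window events for subsampling")
    ev = events.set_index("event_id")
    joined = assignments.join(ev[["category", "fatalities"]], on="event_id")
    if measure == "casualties_vac":
        joined.loc[joined["category"] != "violence_against_civilians", "fatalities"] = 0
    cls = metrics.set_index("city_id")[column]
    event_class = joined["assigned_city"].map(cls).where(
        joined["assigned_city"] != RURAL, other="")
    fat = joined["fatalities"].to_numpy(float)
    num = fat * (event_class == labels[0]).to_numpy()
    den = fat * (event_class == labels[1]).to_numpy()
    pops = cities.merge(metrics[["city_id", column]], on="city_id")
    pop_num = float(pops.loc[pops[column] == labels[0], "population"].sum())
    pop_den = float(pops.loc[pops[column] == labels[1], "population"].sum())
    if pop_num == 0 or pop_den == 0:
        raise AnalysisError("a compared group has no population")
    return num, den, pop_num, pop_den


def subsample_events_theta(events: pd.DataFrame, cities: pd.DataFrame,
                           metrics: pd.DataFrame, params: AssignmentParams,
                           frac: float = 0.5, reps: int = 1000, seed: int = 0,
                           measure: str = "casualties_all",
                           which: str = "isolation") -> SubsampleDistribution:
    """Distribution of theta over random event subsamples.

    For each repetition a uniform ``frac`` of the in-window events is kept
    (without replacement) and theta is recomputed.  ``which`` selects the
    isolation ratio (default) or the centrality-quartile ratio.
    """
    if reps < 1:
        raise AnalysisError(f"reps must be >= 1, got {reps}")
    if not 0 < frac <= 1:
        raise AnalysisError(f"frac must be in (0, 1], got {frac}")
    if which == "isolation":
        column, labels = "isolation_class", ("high", "low")
    elif which == "centrality":
        column, labels = "centrality_class", ("Q1_lowest", "Q4_highest")
    else:
        raise AnalysisError(f"unknown comparison {which!r}")
    num, den, pop_num, pop_den = _event_group_arrays(
        events, cities, metrics, params, column, labels, measure)
    n = len(num)
    n_keep = int(round(frac * n))
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(reps):
        idx = rng.choice(n, size=n_keep, replace=False)
        phi_num = num[idx].sum() / pop_num
        phi_den = den[idx].sum() / pop_den
        samples.append(phi_num / phi_den if phi_den > 0
                       else (float("inf") if phi_num > 0 else float("nan")))
    out = SubsampleDistribution(frac=frac, reps=reps, seed=seed)
    if which == "isolation":
        out.theta_samples = samples
    else:
        out.theta_centrality_samples = samples
    return out


def delta_sweep(events: pd.DataFrame, cities: pd.DataFrame, metrics: pd.DataFrame,
                deltas: list[float], params: AssignmentParams | None = None,
                measure: str = "casualties_all") -> pd.DataFrame:
    """theta_isolation (and theta_centrality if available) for each delta."""
    if not deltas:
        raise AnalysisError("deltas must be nonempty")
    if any(d <= 0 for d in deltas):
        raise AnalysisError("all deltas must be > 0")
    params = params or AssignmentParams()
    has_quartiles = metrics["centrality_class"].isin(["Q1_lowest"]).any()
    rows = []
    for delta in deltas:
        p = with_delta(params, delta)
        assignments = assign_events(events, cities, p)
        cvt = aggregate_city_violence(assignments, events, cities, p)
        rows.append({
            "delta_km": delta,
            "theta_isolation": isolation_impact(cvt, metrics, measure=measure),
            "theta_centrality": (centrality_impact(cvt, metrics, measure=measure)
                                 if has_quartiles else np.nan),
            "measure": measure,
        })
    return pd.DataFrame(rows)
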