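"""Urban-scaling exponent estimation and robustness checks.

The scaling relation ``V = alpha * P^beta`` is fitted by ordinary least
squares of log10(measure) on log10(population) over cities with a positive
measure.  Robustness: refits after dropping the most populous cities
("dragon-kings"), over random city subsamples, and over truncated time
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AnalysisError, UrbisoError
from .event_assignment import (
    AssignmentParams,
    CityViolenceTable,
    aggregate_city_violence,
    assign_events,
)

MEASURES = ("casualties_all", "casualties_vac", "n_events")


@dataclass(frozen=True)
class ScalingFit:
    alpha: float
    beta: float
    beta_se: float
    n_cities_used: int
    n_zero_excluded: int
    measure: str
    delta_km: float | None = None

    @property
    def regime(self) -> str:
        """'sublinear' / 'linear' / 'superlinear' classification of beta."""
        if self.beta < 1.0:
            return "sublinear"
        if self.beta > 1.0:
            return "superlinear"
        return "linear"


@dataclass
class RobustnessResult:
    baseline_beta: float
    betas_without_top_k: list[float] = field(default_factory=list)
    subsample_betas: list[float] = field(default_factory=list)
    frac: float | None = None
    reps: int = 0
    seed: int | None = None


def _fit_loglog(pop: np.ndarray, value: np.ndarray, measure: str,
                delta_km: float | None, n_zero: int) -> ScalingFit:
    x = sm.add_constant(np.log10(pop))
    res = sm.OLS(np.log10(value), x).fit()
    return ScalingFit(
        alpha=float(10.0 ** res.params[0]),
        beta=float(res.params[1]),
        beta_se=float(res.bse[1]),
        n_cities_used=len(pop),
        n_zero_excluded=n_zero,
        measure=measure,
        delta_km=delta_km,
    )


def fit_scaling(table: CityViolenceTable | pd.DataFrame, measure: str = "casualties_all",
                plus_one: bool = False) -> ScalingFit:
    """OLS fit of log10(measure) on log10(population).

    Cities with measure == 0 are excluded (their count is reported on the
    fit); ``plus_one=True`` instead fits log10(measure + 1) over all cities
    as a zero-handling sensitivity check.
    """
    if measure not in MEASURES:
        raise AnalysisError(f"unknown measure {measure!r}")
    df = table.table if isinstance(table, CityViolenceTable) else table
    delta = table.params.delta_km if isinstance(table, CityViolenceTable) else None
    pop = df["population"].to_numpy(float)
    val = df[measure].to_numpy(float)
    if plus_one:
        if len(df) < 3:
            raise AnalysisError("need >= 3 cities to fit")
        return _fit_loglog(pop, val + 1.0, measure, delta, n_zero=0)
    pos = val > 0
    if pos.sum() < 3:
        raise AnalysisError(
            f"need >= 3 cities with positive {measure}, got {int(pos.sum())}")
    return _fit_loglog(pop[pos], val[pos], measure, delta, n_zero=int((~pos).sum()))


def drop_dragon_kings(table: CityViolenceTable, measure: str,
                      k: int) -> RobustnessResult:
    """Refit the scaling law after removing the 1..k most populous cities."""
    df = table.table
    n_positive = int((df[measure] > 0).sum())
    if k < 0 or k >= n_positive - 3:
        raise AnalysisError(f"k must be in [0, {n_positive - 4}], got {k}")
    baseline = fit_scaling(table, measure)
    order = df.sort_values(["population", "city_id"],
                           ascending=[False, True]).index
    betas = []
    for i in range(1, k + 1):
        kept = df.drop(order[:i])
        betas.append(fit_scaling(kept.assign(), measure).beta)
    return RobustnessResult(baseline_beta=baseline.beta, betas_without_top_k=betas)


def subsample_cities(table: CityViolenceTable, measure: str, frac: float,
                     reps: int, seed: int) -> RobustnessResult:
    """Refit the scaling law on ``reps`` uniform city subsamples of size frac·n."""
    if not 0 < frac <= 1:
        raise AnalysisError(f"frac must be in (0, 1], got {frac}")
    df = table.table
    n_keep = int(round(frac * len(df)))
    if frac * (df[measure] > 0).sum() < 3:
        raise AnalysisError("subsample too small: frac * n_positive < 3")
    rng = np.random.default_rng(seed)
    baseline = fit_scaling(table, measure)
    betas = []
    for _ in range(reps):
        idx = rng.choice(len(df), size=n_keep, replace=False)
        betas.append(fit_scaling(df.iloc[idx], measure).beta)
    return RobustnessResult(baseline_beta=baseline.beta, subsample_betas=betas,
                            frac=frac, reps=reps, seed=seed)


def beta_by_start_year(events: pd.DataFrame, cities: pd.DataFrame,
                       params: AssignmentParams,
                       start_years: list[int]) -> pd.DataFrame:
    """Scaling exponents restricted to events from each start year onward.

    For every year the window start moves to Jan 1 of that year (window end
    fixed), assignment and aggregation are rerun, and both the all-casualty
    and the violence-against-civilians exponents are refitted.  Years whose
    truncated window cannot be fitted get an ``error`` entry instead.
    """
    rows = []
    for year in start_years:
        row: dict = {"start_year": year, "beta_L": np.nan, "beta_L_se": np.nan,
                     "beta_V": np.nan, "beta_V_se": np.nan, "error": ""}
        try:
            p = replace(params, window_start=pd.Timestamp(year=year, month=1, day=1))
            assignments = assign_events(events, cities, p)
            cvt = aggregate_city_violence(assignments, events, cities, p)
            fit_l = fit_scaling(cvt, "casualties_all")
            fit_v = fit_scaling(cvt, "casualties_vac")
            row.update(beta_L=fit_l.beta, beta_L_se=fit_l.beta_se,
                       beta_V=fit_v.beta, beta_V_se=fit_v.beta_se)
        except UrbisoError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
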