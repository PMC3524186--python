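"""Annual drought-intensity indices from monthly drought-severity series.

A location's monthly Palmer-type drought-severity values (``q``, standardized
wetness scale, negative = dry) are reduced to annual indices:

* ``T``    — total months of the year with ``q`` below the location threshold;
* ``C``    — longest run of consecutive sub-threshold months within the year;
* ``T_t2`` / ``C_t2`` — the same over the 24-month window (year-1, year),
  with runs allowed to cross the December/January boundary;
* ``drought_year`` — true whenever at least one month is sub-threshold.

The threshold ``theta`` is a low percentile (10th by default) of the
location's reference distribution of monthly values, so a "drought year"
contains at least one month that is rare within the local climatology.
Annual drought/non-drought sequences are further summarized as alternating
episode (run) lengths and as the parameters of a two-state Markov chain:
the probability a year is in drought (``p_init``), the drought persistence
probability (``ddt``), the non-drought persistence probability (``nddt``)
and the empirical distribution of within-year drought lengths ``C``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyDroughtSeries",
    "DroughtThreshold",
    "AnnualDroughtIndices",
    "RunLengthStats",
    "MarkovDroughtParams",
    "compute_threshold",
    "flag_drought_months",
    "annual_indices",
    "annual_indices_table",
    "run_lengths",
    "estimate_markov_params",
    "grid_cell_lookup",
    "annual_summary_pdsi",
]


@dataclass(frozen=True)
class MonthlyDroughtSeries:
    """Ordered monthly drought-severity values for one location.

    ``data`` has columns ``year``, ``month``, ``q``; missing months are
    represented by NaN in ``q``. (year, month) must be strictly increasing.
    """

    location_id: str
    lat: float
    lon: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"year", "month", "q"}
        if not required.issubset(df.columns):
            raise ValueError(f"series data needs columns {sorted(required)}")
        key = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
        if len(key) and np.any(np.diff(key) <= 0):
            raise ValueError(
                f"location {self.location_id}: (year, month) must be strictly "
                "increasing with no duplicates"
            )
        if ((df["month"] < 1) | (df["month"] > 12)).any():
            raise ValueError("month must be in 1..12")

    def year_values(self, year: int) -> np.ndarray:
        """The q values of calendar `year`, NaN-padded to 12 months."""
        sub = self.data[self.data["year"] == year]
        out = np.full(12, np.nan)
        out[sub["month"].to_numpy() - 1] = sub["q"].to_numpy()
        return out

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())


@dataclass(frozen=True)
class DroughtThreshold:
    """Percentile-based drought threshold for one location."""

    location_id: str
    theta: float
    percentile: float = 10.0
    reference_period: tuple[int, int] | None = None
    n_reference_months: int = 0


@dataclass(frozen=True)
class AnnualDroughtIndices:
    """Drought-intensity indices for one location-year.

    ``T_t2``/``C_t2`` are None when the preceding year is unavailable;
    all four are None when the year had too many missing months.
    """

    location_id: str
    year: int
    T: int | None
    C: int | None
    T_t2: int | None = None
    C_t2: int | None = None

    @property
    def drought_year(self) -> bool | None:
        if self.T is None:
            return None
        return self.T >= 1


@dataclass(frozen=True)
class RunLengthStats:
    """Alternating drought / non-drought episode lengths in years."""

    drought_run_lengths: list[int]
    nondrought_run_lengths: list[int]
    mean_recurrence_interval: float | None

    @property
    def n_years(self) -> int:
        return sum(self.drought_run_lengths) + sum(self.nondrought_run_lengths)


@dataclass(frozen=True)
class MarkovDroughtParams:
    """Two-state Markov drought generator parameters.

    p_init: marginal probability a year is in drought; ddt / nddt: the
    probabilities that a drought / non-drought year is followed by a year of
    the same state; length_dist: probability vector over drought lengths of
    1..12 months, indexed so length_dist[k] is P(length = k+1).
    """

    p_init: float
    ddt: float
    nddt: float
    length_dist: np.ndarray = field(
        default_factory=lambda: np.full(12, 1.0 / 12.0)
    )

    def __post_init__(self) -> None:
        for name in ("p_init", "ddt", "nddt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        dist = np.asarray(self.length_dist, dtype=float)
        if dist.ndim != 1 or len(dist) != 12:
            raise ValueError("length_dist must have 12 entries (lengths 1..12)")
        if (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-12:
            raise ValueError("length_dist must be a probability vector")
        object.__setattr__(self, "length_dist", dist)

    @property
    def stationary_drought_frequency(self) -> float:
        """Long-run fraction of drought years, (1-nddt)/((1-nddt)+(1-ddt))."""
        p_enter, p_exit = 1.0 - self.nddt, 1.0 - self.ddt
        if p_enter + p_exit == 0.0:  # both states absorbing
            return self.p_init
        return p_enter / (p_enter + p_exit)


def compute_threshold(
    series: MonthlyDroughtSeries,
    percentile: float = 10.0,
    reference_period: tuple[int, int] | None = None,
    min_reference_months: int = 120,
) -> DroughtThreshold:
    """Percentile of the location's reference distribution of monthly q.

    The reference distribution is all non-missing months of the series,
    optionally restricted to ``reference_period`` (inclusive year bounds).
    Linear interpolation between closest order statistics.
    """
    df = series.data
    if reference_period is not None:
        lo, hi = reference_period
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    q = df["q"].to_numpy(dtype=float)
    q = q[np.isfinite(q)]
    if len(q) < min_reference_months:
        raise ValueError(
            f"location {series.location_id}: only {len(q)} non-missing "
            f"reference months, need at least {min_reference_months}"
        )
    theta = float(np.percentile(q, percentile, method="linear"))
    return DroughtThreshold(
        location_id=series.location_id,
        theta=theta,
        percentile=percentile,
        reference_period=reference_period,
        n_reference_months=len(q),
    )


def flag_drought_months(
    series: MonthlyDroughtSeries, threshold: DroughtThreshold
) -> pd.DataFrame:
    """Flag each month as drought iff q is strictly below theta.

    Missing months are flagged False and counted. Returns a frame with
    columns ``year, month, drought, missing``; ties at theta are non-drought.
    """
    if threshold.location_id != series.location_id:
        raise ValueError(
            f"threshold is for {threshold.location_id!r}, "
            f"series is {series.location_id!r}"
        )
    q = series.data["q"].to_numpy(dtype=float)
    missing = ~np.isfinite(q)
    drought = np.where(missing, False, q < threshold.theta)
    return pd.DataFrame(
        {
            "year": series.data["year"].to_numpy(),
            "month": series.data["month"].to_numpy(),
            "drought": drought.astype(bool),
            "missing": missing,
        }
    )


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def _year_flags(flags: pd.DataFrame, year: int) -> tuple[np.ndarray, int] | None:
    """12 monthly booleans for `year` plus its missing count; None if absent."""
    sub = flags[flags["year"] == year]
    if len(sub) == 0:
        return None
    out = np.zeros(12, dtype=bool)
    out[sub["month"].to_numpy() - 1] = sub["drought"].to_numpy()
    n_missing = int(sub["missing"].sum()) + (12 - len(sub))
    return out, n_missing


def annual_indices(
    flags: pd.DataFrame,
    year: int,
    location_id: str = "",
    max_missing_months: int = 3,
) -> AnnualDroughtIndices:
    """Compute T, C, T_t2, C_t2 for one calendar year from monthly flags.

    The two-year indices use the 24-month window (year-1, year) and runs may
    cross the year boundary. A year with more than ``max_missing_months``
    missing months yields absent (None) indices; a missing preceding year
    yields absent two-year indices only.
    """
    cur = _year_flags(flags, year)
    if cur is None:
        raise ValueError(f"year {year} absent from flags")
    cur_flags, cur_missing = cur
    if cur_missing > max_missing_months:
        return AnnualDroughtIndices(location_id, year, None, None, None, None)
    T = int(cur_flags.sum())
    C = _longest_run(cur_flags)
    prev = _year_flags(flags, year - 1)
    if prev is None or prev[1] > max_missing_months:
        return AnnualDroughtIndices(location_id, year, T, C, None, None)
    window = np.concatenate([prev[0], cur_flags])
    return AnnualDroughtIndices(
        location_id, year, T, C, int(window.sum()), _longest_run(window)
    )


def annual_indices_table(
    series: MonthlyDroughtSeries,
    threshold: DroughtThreshold | None = None,
    percentile: float = 10.0,
    max_missing_months: int = 3,
) -> pd.DataFrame:
    """Indices for every year of a series as a frame.

    Columns: ``location_id, year, T, C, T_t2, C_t2, drought_year``; absent
    values are NA (pandas nullable Int64 / boolean).
    """
    if threshold is None:
        threshold = compute_threshold(series, percentile=percentile)
    flags = flag_drought_months(series, threshold)
    rows = []
    for year in series.years:
        idx = annual_indices(
            flags, year, series.location_id, max_missing_months=max_missing_months
        )
        rows.append(
            {
                "location_id": idx.location_id,
                "year": idx.year,
                "T": idx.T,
                "C": idx.C,
                "T_t2": idx.T_t2,
                "C_t2": idx.C_t2,
                "drought_year": idx.drought_year,
            }
        )
    out = pd.DataFrame(rows)
    for col in ("T", "C", "T_t2", "C_t2"):
        out[col] = out[col].astype("Int64")
    out["drought_year"] = out["drought_year"].astype("boolean")
    return out


def run_lengths(drought_years: Sequence[bool]) -> RunLengthStats:
    """Decompose an annual drought/non-drought sequence into episode lengths.

    Also reports the mean recurrence interval: the average distance in years
    between successive drought years (None when fewer than two drought years).
    """
    flags = [bool(f) for f in drought_years]
    if len(flags) < 2:
        raise ValueError("need at least 2 classified years")
    droughts: list[int] = []
    nondroughts: list[int] = []
    cur_state, cur_len = flags[0], 1
    for f in flags[1:]:
        if f == cur_state:
            cur_len += 1
        else:
            (droughts if cur_state else nondroughts).append(cur_len)
            cur_state, cur_len = f, 1
    (droughts if cur_state else nondroughts).append(cur_len)

    positions = [i for i, f in enumerate(flags) if f]
    if len(positions) >= 2:
        gaps = np.diff(positions)
        recurrence: float | None = float(np.mean(gaps))
    else:
        recurrence = None
    return RunLengthStats(droughts, nondroughts, recurrence)


def estimate_markov_params(
    drought_year_sequences: Iterable[Sequence[bool]],
    drought_year_c_values: Sequence[int] | None = None,
) -> MarkovDroughtParams:
    """Estimate the two-state Markov drought parameters from annual flags.

    Transitions are pooled across the given location sequences (no transition
    is counted across the join between two locations). ``drought_year_c_values``
    are the within-year drought lengths C (1..12 months) observed in drought
    years; when given, they define the empirical length distribution.
    """
    n_years = n_drought = 0
    from_d = dd = from_n = nn = 0
    for seq in drought_year_sequences:
        flags = [bool(f) for f in seq]
        n_years += len(flags)
        n_drought += sum(flags)
        for a, b in zip(flags[:-1], flags[1:]):
            if a:
                from_d += 1
                dd += b
            else:
                from_n += 1
                nn += not b
    if n_years == 0:
        raise ValueError("no years supplied")
    if from_d == 0:
        raise ValueError("no transitions out of the drought state observed")
    if from_n == 0:
        raise ValueError("no transitions out of the non-drought state observed")

    if drought_year_c_values is not None and len(drought_year_c_values) > 0:
        c = np.asarray(drought_year_c_values, dtype=int)
        if ((c < 1) | (c > 12)).any():
            raise ValueError("drought lengths C must be in 1..12 months")
        counts = np.bincount(c, minlength=13)[1:13].astype(float)
        length_dist = counts / counts.sum()
    else:
        length_dist = np.full(12, 1.0 / 12.0)

    return MarkovDroughtParams(
        p_init=n_drought / n_years,
        ddt=dd / from_d,
        nddt=nn / from_n,
        length_dist=length_dist,
    )


def grid_cell_lookup(
    lat: float, lon: float, cell_size: float = 2.5
) -> tuple[int, int]:
    """Index of the grid cell containing a point.

    Cells are half-open, lower-edge inclusive, with origin (-90, -180);
    the north pole and the antimeridian clamp to the last cell. Returns
    (lat_index, lon_index).
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    n_lat = int(round(180.0 / cell_size))
    n_lon = int(round(360.0 / cell_size))
    i = min(int(math.floor((lat + 90.0) / cell_size)), n_lat - 1)
    j = min(int(math.floor((lon + 180.0) / cell_size)), n_lon - 1)
    return i, j


def annual_summary_pdsi(
    series: MonthlyDroughtSeries, year: int
) -> tuple[float, float]:
    """(annual mean q, annual modal q) for one calendar year.

    The mode of 12 continuous values is taken over values rounded to one
    decimal, ties broken toward the lower value. Missing months are dropped
    (the summaries then cover the available months only).
    """
    values = series.year_values(year)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError(f"year {year}: no non-missing months")
    mean = float(np.mean(values))
    rounded = np.round(values, 1)
    uniq, counts = np.unique(rounded, axis=0, return_counts=True)
    mode = float(uniq[counts == counts.max()].min())
    return mean, mode
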