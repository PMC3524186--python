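"""Abundance time series: growth rates, filtering rules, life-history groups.

Yearly abundance records (Living-Planet-Index style: one population of one
species at one location, censused in some subset of years) are turned into
per-year log growth rates r_t = ln(N_{t+1}/N_t), computed only for pairs of
consecutive-year censuses. Several quality filters are applied before any
regression:

* species with 20 or fewer pooled growth observations are dropped;
* populations whose first abundance record is below the species' herd-size
  range are dropped (unstable / fragmentary populations);
* observations with growth above the species' physiological ceiling
  r_max = ln(1 + max offspring per female per year) are dropped (an
  all-female, no-mortality population cannot grow faster);
* explicitly listed populations (management, poaching, mixed sources) are
  excluded via an exclusion table rather than inferred.

Species are assigned to four life-history groups crossing movement
(sedentary S vs mobile/non-sedentary M) with diet (grazer-or-mixed G, the
drought-intolerant-forage side, vs browser-or-omnivore B): SG, SB, MG, MB.
"""

from __future__ import annotations

import logging

import pandas as pd

from .drought_indices import grid_cell_lookup

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "MOVEMENT_CLASSES",
    "DIET_CLASSES",
    "compute_growth_rates",
    "filter_min_observations",
    "filter_initial_abundance",
    "max_growth_filter",
    "apply_exclusions",
    "assign_group",
    "add_groups",
    "join_drought",
    "max_growth_rate",
]

GROUPS = ("SG", "SB", "MG", "MB")
MOVEMENT_CLASSES = ("sedentary", "non_sedentary")
DIET_CLASSES = ("grazer", "mixed", "browser", "omnivore")

_RECORD_COLS = ["population_id", "species", "location_id", "lat", "lon", "year", "abundance"]


def compute_growth_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year log growth rates from consecutive-year census pairs.

    One observation per pair of censuses in years (t, t+1):
    r = ln(N_{t+1} / N_t). Pairs separated by a gap of two or more years
    produce nothing; pairs with a zero abundance on either side are skipped
    with a warning (the log is undefined).

    Returns columns ``population_id, species, location_id, lat, lon, year, r``
    where ``year`` is t, the first year of the interval.
    """
    import numpy as np

    missing = [c for c in _RECORD_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if (records["abundance"] < 0).any():
        raise ValueError("negative abundance")

    out = []
    for pid, grp in records.sort_values("year").groupby("population_id", sort=False):
        years = grp["year"].to_numpy()
        n = grp["abundance"].to_numpy(dtype=float)
        consecutive = np.where(np.diff(years) == 1)[0]
        for i in consecutive:
            if n[i] <= 0 or n[i + 1] <= 0:
                logger.warning(
                    "population %s: zero abundance in pair %d-%d, skipped",
                    pid, years[i], years[i] + 1,
                )
                continue
            out.append(
                {
                    "population_id": pid,
                    "species": grp["species"].iloc[0],
                    "location_id": grp["location_id"].iloc[0],
                    "lat": grp["lat"].iloc[0],
                    "lon": grp["lon"].iloc[0],
                    "year": int(years[i]),
                    "r": float(np.log(n[i + 1] / n[i])),
                }
            )
    cols = ["population_id", "species", "location_id", "lat", "lon", "year", "r"]
    return pd.DataFrame(out, columns=cols)


def filter_min_observations(
    observations: pd.DataFrame, threshold: int = 20
) -> pd.DataFrame:
    """Keep species with strictly more than `threshold` pooled observations."""
    if len(observations) == 0:
        return observations
    counts = observations.groupby("species")["r"].size()
    keep = counts[counts > threshold].index
    return observations[observations["species"].isin(keep)].reset_index(drop=True)


def _check_traits(df: pd.DataFrame, species: pd.Series) -> None:
    unknown = sorted(set(species) - set(df["species"]))
    if unknown:
        raise ValueError(f"species missing from trait table: {unknown}")


def filter_initial_abundance(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    bound: str = "min",
) -> pd.DataFrame:
    """Drop whole populations whose first census is below the herd-size range.

    ``bound`` selects the comparison point within the species' herd-size
    range: ``"min"`` (lower bound, the permissive default) or ``"midpoint"``.
    """
    if bound not in ("min", "midpoint"):
        raise ValueError("bound must be 'min' or 'midpoint'")
    _check_traits(traits, records["species"])
    t = traits.set_index("species")
    if bound == "min":
        cutoff = t["herd_size_min"]
    else:
        cutoff = (t["herd_size_min"] + t["herd_size_max"]) / 2.0

    first = records.sort_values("year").groupby("population_id").first()
    bad = first.index[
        first["abundance"] < cutoff.loc[first["species"]].to_numpy()
    ]
    return records[~records["population_id"].isin(bad)].reset_index(drop=True)


def max_growth_rate(max_offspring_per_female_per_year: float) -> float:
    """Physiological ceiling ln(1 + f): all-female, maximal birth, no death."""
    import numpy as np

    return float(np.log1p(max_offspring_per_female_per_year))


def max_growth_filter(
    observations: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Remove observations with r above the species' physiological ceiling.

    The rule is one-sided: arbitrarily negative growth is retained.
    """
    _check_traits(traits, observations["species"])
    ceiling = traits.set_index("species")["max_offspring_per_female_per_year"].map(
        max_growth_rate
    )
    r_max = observations["species"].map(ceiling).to_numpy()
    over = observations["r"].to_numpy() > r_max
    if over.any():
        logger.info("removed %d observations above the growth ceiling", over.sum())
    return observations[~over].reset_index(drop=True)


def apply_exclusions(
    records: pd.DataFrame, exclusions: pd.DataFrame | None
) -> pd.DataFrame:
    """Drop populations listed in an exclusion table (`population_id, reason`)."""
    if exclusions is None or len(exclusions) == 0:
        return records
    return records[
        ~records["population_id"].isin(exclusions["population_id"])
    ].reset_index(drop=True)


def assign_group(movement: str, diet: str) -> str:
    """Life-history group from movement x diet.

    Grazers and mixed feeders form the drought-intolerant-forage (G) side;
    browsers and omnivores the B side. Sedentary species are S, others M.
    """
    if movement not in MOVEMENT_CLASSES:
        raise ValueError(f"unknown movement class {movement!r}, expected one of {MOVEMENT_CLASSES}")
    if diet not in DIET_CLASSES:
        raise ValueError(f"unknown diet class {diet!r}, expected one of {DIET_CLASSES}")
    side = "S" if movement == "sedentary" else "M"
    feed = "G" if diet in ("grazer", "mixed") else "B"
    return side + feed


def add_groups(traits: pd.DataFrame) -> pd.DataFrame:
    """Trait table with a `group` column appended."""
    out = traits.copy()
    out["group"] = [
        assign_group(m, d) for m, d in zip(out["movement"], out["diet"])
    ]
    return out


def join_drought(
    observations: pd.DataFrame,
    indices: pd.DataFrame,
    cell_size: float = 2.5,
) -> pd.DataFrame:
    """Attach each growth observation's drought indices for its year t.

    The observation for the interval t -> t+1 carries the drought indices of
    calendar year t (the interval's first year). Populations are mapped to
    grid cells by coordinates when the index table carries lat/lon, otherwise
    joined on ``location_id`` directly. Populations whose cell or location is
    absent from the index table raise.
    """
    obs = observations.copy()
    value_cols = ["year", "T", "C", "T_t2", "C_t2", "drought_year"]
    if {"lat", "lon"}.issubset(indices.columns):
        idx = indices.copy()
        idx["_cell"] = [
            grid_cell_lookup(la, lo, cell_size) for la, lo in zip(idx["lat"], idx["lon"])
        ]
        obs["_cell"] = [
            grid_cell_lookup(la, lo, cell_size) for la, lo in zip(obs["lat"], obs["lon"])
        ]
        key = "_cell"
        idx = idx.drop_duplicates(subset=["_cell", "year"])
    else:
        idx = indices
        key = "location_id"
    known = set(idx[key])
    orphans = obs.loc[~obs[key].isin(known), "population_id"].unique()
    if len(orphans):
        raise ValueError(
            f"no drought indices for populations: {sorted(map(str, orphans))}"
        )
    merged = obs.merge(idx[[key] + value_cols], on=[key, "year"], how="left")
    if "_cell" in merged:
        merged = merged.drop(columns="_cell")
    return merged
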