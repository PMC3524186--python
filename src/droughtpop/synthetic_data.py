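"""Synthetic inputs with the statistical structure the analysis assumes.

The real inputs — gridded monthly drought-severity values and confidential
Living-Planet-Index abundance series — cannot be redistributed, so this
module generates stand-ins with known ground truth:

* monthly drought-severity series per location as a stationary Gaussian
  AR(1) process (the simplest process with PDSI-like month-to-month
  persistence; the default coefficient is tuned so that 10th-percentile
  thresholding yields drought / non-drought year runs with pseudomedians
  near 2 and 3 years, the magnitudes typical of semi-arid Africa);
* an ungulate trait table covering all four life-history groups;
* abundance records generated from the same model the analysis fits:
  log-abundance random walk with drift a + b*C_year plus location and
  species random intercepts, multiplicative log-normal observation noise,
  and censuses dropped independently with a gap probability (irregular
  yearly surveys, 1970-2005).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drought_indices import MonthlyDroughtSeries
from .population_records import assign_group

__all__ = [
    "SyntheticWorldSpec",
    "generate_pdsi",
    "generate_traits",
    "generate_populations",
    "generate_world",
]

# Semi-arid southern/eastern Africa study window.
_LAT_RANGE = (-30.0, 0.0)
_LON_RANGE = (15.0, 40.0)


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Ground-truth configuration for the synthetic world.

    The default monthly AR(1) coefficient 0.88 gives drought-severity
    persistence such that annual drought classification at the 10th
    percentile produces episode lengths comparable to the observed
    pseudomedians (~2-year droughts, ~3-year non-drought spells).
    """

    n_locations: int = 6
    start_year: int = 1969  # one spin-up year so two-year indices exist in 1970
    end_year: int = 2005
    phi: float = 0.88
    innovation_sd: float = 1.0
    a_by_species: dict[str, float] = field(
        default_factory=lambda: {"synthetic_ungulate_1": 0.05}
    )
    b_by_group: dict[str, float] = field(default_factory=lambda: {"SG": -0.04})
    location_intercept_sd: float = 0.02
    species_intercept_sd: float = 0.02
    observation_noise_sd: float = 0.05
    census_gap_probability: float = 0.1
    n0_range: tuple[float, float] = (200.0, 2000.0)
    populations_per_species: int = 6
    seed: int = 20120

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1 for stationarity")
        if not 0.0 <= self.census_gap_probability < 1.0:
            raise ValueError("census gap probability must be in [0, 1)")
        for name in ("innovation_sd", "location_intercept_sd",
                     "species_intercept_sd", "observation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(spec: SyntheticWorldSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def generate_pdsi(spec: SyntheticWorldSpec) -> list[MonthlyDroughtSeries]:
    """Stationary AR(1) monthly drought-severity series, one per location.

    q_t = phi * q_{t-1} + eps_t, eps ~ N(0, innovation_sd^2); the initial
    value is drawn from the stationary marginal so the series needs no
    burn-in. Locations are independent.
    """
    rng = _rng(spec, 1)
    n_months = (spec.end_year - spec.start_year + 1) * 12
    years = np.repeat(np.arange(spec.start_year, spec.end_year + 1), 12)
    months = np.tile(np.arange(1, 13), spec.end_year - spec.start_year + 1)
    stationary_sd = spec.innovation_sd / np.sqrt(1.0 - spec.phi**2)
    out = []
    for i in range(spec.n_locations):
        lat = rng.uniform(*_LAT_RANGE)
        lon = rng.uniform(*_LON_RANGE)
        eps = rng.normal(0.0, spec.innovation_sd, n_months)
        q = np.empty(n_months)
        q[0] = rng.normal(0.0, stationary_sd)
        for t in range(1, n_months):
            q[t] = spec.phi * q[t - 1] + eps[t]
        out.append(
            MonthlyDroughtSeries(
                location_id=f"loc{i:02d}",
                lat=float(lat),
                lon=float(lon),
                data=pd.DataFrame({"year": years, "month": months, "q": q}),
            )
        )
    return out


def generate_traits(spec: SyntheticWorldSpec) -> pd.DataFrame:
    """A trait table covering all four movement x diet groups.

    Species named in ``a_by_species`` are assigned to groups round-robin in
    the order SG, SB, MG, MB; four extra fixed species guarantee every group
    is represented. Herd sizes and offspring caps are plausible for
    medium-sized ungulates.
    """
    combos = [
        ("sedentary", "grazer"),        # SG
        ("sedentary", "browser"),       # SB
        ("non_sedentary", "mixed"),     # MG
        ("non_sedentary", "omnivore"),  # MB
    ]
    rows = []
    for i, sp in enumerate(spec.a_by_species):
        movement, diet = combos[i % 4]
        rows.append((sp, movement, diet))
    for i, (movement, diet) in enumerate(combos):
        sp = f"synthetic_filler_{assign_group(movement, diet)}"
        if not any(r[1] == movement and r[2] == diet for r in rows):
            rows.append((sp, movement, diet))
    df = pd.DataFrame(rows, columns=["species", "movement", "diet"])
    df["herd_size_min"] = 10
    df["herd_size_max"] = 50
    df["max_offspring_per_female_per_year"] = 1
    df["group"] = [assign_group(m, d) for m, d in zip(df["movement"], df["diet"])]
    return df


def generate_populations(
    spec: SyntheticWorldSpec,
    indices: pd.DataFrame,
    traits: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Abundance records driven by the location's drought indices.

    For each population (species x location draw), true log abundance
    follows ln N_{t+1} = ln N_t + a_species + b_group * C_t + u_loc + v_sp,
    observed abundance adds log-normal noise, and each census survives
    independently with probability 1 - gap. Returns the records plus the
    ground-truth parameter table.

    ``indices`` must carry columns ``location_id, year, C`` for every
    location used (years with absent C contribute no drought effect).
    """
    if traits is None:
        traits = generate_traits(spec)
    rng = _rng(spec, 2)
    traits = traits.set_index("species")
    locations = sorted(indices["location_id"].unique())
    c_table = {
        (row.location_id, int(row.year)): row.C
        for row in indices.itertuples()
    }
    u_loc = {
        loc: rng.normal(0.0, spec.location_intercept_sd) for loc in locations
    }
    v_sp = {
        sp: rng.normal(0.0, spec.species_intercept_sd)
        for sp in spec.a_by_species
    }

    loc_coords = (
        indices.drop_duplicates("location_id").set_index("location_id")
        if {"lat", "lon"}.issubset(indices.columns)
        else None
    )

    records = []
    truth_rows = []
    pid = 0
    years = np.arange(spec.start_year + 1, spec.end_year + 1)
    for sp, a in spec.a_by_species.items():
        group = traits.loc[sp, "group"]
        b = spec.b_by_group.get(group, 0.0)
        for _ in range(spec.populations_per_species):
            loc = locations[rng.integers(len(locations))]
            n0 = rng.uniform(*spec.n0_range)
            log_n = np.log(n0)
            drift = a + u_loc[loc] + v_sp[sp]
            pid += 1
            pop_id = f"pop{pid:03d}"
            if loc_coords is not None:
                lat = float(loc_coords.loc[loc, "lat"])
                lon = float(loc_coords.loc[loc, "lon"])
            else:
                lat = lon = 0.0
            truth_rows.append(
                {
                    "population_id": pop_id,
                    "species": sp,
                    "location_id": loc,
                    "group": group,
                    "a": a,
                    "b": b,
                    "u_location": u_loc[loc],
                    "v_species": v_sp[sp],
                    "n0": n0,
                }
            )
            for year in years:
                c = c_table.get((loc, int(year)))
                c_eff = 0.0 if c is None or pd.isna(c) else float(c)
                if rng.uniform() >= spec.census_gap_probability:
                    obs = np.exp(log_n + rng.normal(0.0, spec.observation_noise_sd))
                    records.append(
                        {
                            "population_id": pop_id,
                            "species": sp,
                            "location_id": loc,
                            "lat": lat,
                            "lon": lon,
                            "year": int(year),
                            "abundance": obs,
                        }
                    )
                log_n += drift + b * c_eff

    truth = {
        "populations": pd.DataFrame(truth_rows),
        "a_by_species": dict(spec.a_by_species),
        "b_by_group": dict(spec.b_by_group),
        "spec": spec,
    }
    return pd.DataFrame(records), truth


def generate_world(
    spec: SyntheticWorldSpec | None = None,
) -> dict:
    """Full synthetic study: PDSI series, indices, traits, abundance records.

    Convenience wrapper running the whole generation chain; returns a dict
    with keys ``series, indices, traits, records, truth``.
    """
    from .drought_indices import annual_indices_table

    spec = spec or SyntheticWorldSpec()
    series = generate_pdsi(spec)
    idx = []
    for s in series:
        tab = annual_indices_table(s)
        tab["lat"] = s.lat
        tab["lon"] = s.lon
        idx.append(tab)
    indices = pd.concat(idx, ignore_index=True)
    traits = generate_traits(spec)
    records, truth = generate_populations(spec, indices, traits)
    return {
        "series": series,
        "indices": indices,
        "traits": traits,
        "records": records,
        "truth": truth,
    }
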