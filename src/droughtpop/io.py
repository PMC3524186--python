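"""Readers and writers for the pipeline's file formats.

Long-format CSV is the primary interchange format; a NetCDF reader is
provided for gridded (time, lat, lon) drought-severity data. Markov
parameters round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drought_indices import MarkovDroughtParams, MonthlyDroughtSeries

__all__ = [
    "read_pdsi_csv",
    "write_pdsi_csv",
    "read_pdsi_netcdf",
    "read_records_csv",
    "read_traits_csv",
    "write_indices_csv",
    "read_indices_csv",
    "write_markov_yaml",
    "read_markov_yaml",
]

PDSI_COLUMNS = ["location_id", "lat", "lon", "year", "month", "pdsi"]
RECORD_COLUMNS = ["population_id", "species", "location_id", "lat", "lon", "year", "abundance"]
TRAIT_COLUMNS = [
    "species", "movement", "diet",
    "herd_size_min", "herd_size_max", "max_offspring_per_female_per_year",
]


def read_pdsi_csv(path: str | Path) -> list[MonthlyDroughtSeries]:
    """Monthly drought-severity series from long-format CSV.

    Expected header: ``location_id,lat,lon,year,month,pdsi``; empty pdsi
    fields are missing months.
    """
    df = pd.read_csv(path)
    missing = [c for c in PDSI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for loc, grp in df.groupby("location_id", sort=True):
        grp = grp.sort_values(["year", "month"])
        out.append(
            MonthlyDroughtSeries(
                location_id=str(loc),
                lat=float(grp["lat"].iloc[0]),
                lon=float(grp["lon"].iloc[0]),
                data=grp[["year", "month"]].assign(q=grp["pdsi"].to_numpy())
                .reset_index(drop=True),
            )
        )
    return out


def write_pdsi_csv(series: list[MonthlyDroughtSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        df = s.data.rename(columns={"q": "pdsi"}).copy()
        df.insert(0, "location_id", s.location_id)
        df.insert(1, "lat", s.lat)
        df.insert(2, "lon", s.lon)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[PDSI_COLUMNS].to_csv(path, index=False)


def read_pdsi_netcdf(
    path: str | Path, var: str = "pdsi"
) -> list[MonthlyDroughtSeries]:
    """Gridded monthly drought-severity values from a NetCDF file.

    Expects a (time, lat, lon) variable with a CF-style monthly time axis;
    each grid cell with any finite value becomes one series, with
    location_id "cell_<i>_<j>".
    """
    import xarray as xr

    ds = xr.open_dataset(path)
    da = ds[var]
    times = pd.DatetimeIndex(da["time"].to_index())
    out = []
    for i, lat in enumerate(np.asarray(da["lat"])):
        for j, lon in enumerate(np.asarray(da["lon"])):
            vals = np.asarray(da.isel(lat=i, lon=j))
            if not np.isfinite(vals).any():
                continue
            out.append(
                MonthlyDroughtSeries(
                    location_id=f"cell_{i}_{j}",
                    lat=float(lat),
                    lon=float(lon),
                    data=pd.DataFrame(
                        {"year": times.year, "month": times.month, "q": vals}
                    ),
                )
            )
    ds.close()
    return out


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_indices_csv(indices: pd.DataFrame, path: str | Path) -> None:
    cols = ["location_id", "year", "T", "C", "T_t2", "C_t2", "drought_year"]
    extra = [c for c in ("lat", "lon") if c in indices.columns]
    indices[cols + extra].to_csv(path, index=False)


def read_indices_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("T", "C", "T_t2", "C_t2"):
        df[col] = df[col].astype("Int64")
    df["drought_year"] = df["drought_year"].astype("boolean")
    return df


def write_markov_yaml(params: MarkovDroughtParams, path: str | Path) -> None:
    payload = {
        "p_init": float(params.p_init),
        "ddt": float(params.ddt),
        "nddt": float(params.nddt),
        "length_dist": [float(p) for p in params.length_dist],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_markov_yaml(path: str | Path) -> MarkovDroughtParams:
    payload = yaml.safe_load(Path(path).read_text())
    return MarkovDroughtParams(
        p_init=payload["p_init"],
        ddt=payload["ddt"],
        nddt=payload["nddt"],
        length_dist=np.asarray(payload["length_dist"], dtype=float),
    )
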