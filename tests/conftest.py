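import numpy as np
import pandas as pd
import pytest

from droughtpop.drought_indices import MonthlyDroughtSeries
from droughtpop.synthetic_data import SyntheticWorldSpec, generate_world


def make_series(q, start_year=1990, location_id="loc", lat=-12.0, lon=25.0):
    """A MonthlyDroughtSeries from a flat array of monthly q values."""
    q = np.asarray(q, dtype=float)
    n = len(q)
    years = start_year + np.arange(n) // 12
    months = np.arange(n) % 12 + 1
    return MonthlyDroughtSeries(
        location_id, lat, lon,
        pd.DataFrame({"year": years, "month": months, "q": q}),
    )


def flags_frame(year_to_flags, missing=None):
    """Monthly drought-flag frame from {year: 12 booleans}."""
    rows = []
    for year, flags in year_to_flags.items():
        for m, f in enumerate(flags, start=1):
            rows.append(
                {
                    "year": year,
                    "month": m,
                    "drought": bool(f),
                    "missing": bool(missing and (year, m) in missing),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study shared across tests (deterministic)."""
    spec = SyntheticWorldSpec(
        n_locations=4,
        a_by_species={f"synthetic_ungulate_{i}": 0.05 for i in range(1, 5)},
        b_by_group={g: -0.04 for g in ("SG", "SB", "MG", "MB")},
        populations_per_species=2,
        start_year=1969,
        end_year=2005,
        seed=11,
    )
    return generate_world(spec)
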