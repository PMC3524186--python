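"""Model checking: abundance r-squared and episode-length pseudomedians.

Fits the projection model to one synthetic population's observed window,
scores the per-replicate r-squared against the observed abundances, and
checks that a Markov chain estimated from the observed drought flags
reproduces the observed drought / non-drought episode lengths.
"""

import numpy as np

from droughtpop import (
    annual_indices_table,
    episode_length_check,
    estimate_markov_params,
    r_squared_fit,
    run_lengths,
)
from droughtpop.projection import (
    SimulationConfig,
    SimulatorParams,
    project_population,
    step_drought,
)
from droughtpop.synthetic_data import SyntheticWorldSpec, generate_pdsi, generate_world

world = generate_world(SyntheticWorldSpec(n_locations=4, seed=19))
records = world["records"]
pop = records[records["population_id"] == "pop001"].sort_values("year")

# estimate the drought generator from the population's own location
loc = pop["location_id"].iloc[0]
tab = world["indices"].query("location_id == @loc").dropna(subset=["drought_year"])
flags = tab["drought_year"].astype(bool).tolist()
markov = estimate_markov_params(
    [flags], tab.loc[tab["drought_year"] == True, "C"].astype(int).tolist()
)

params = SimulatorParams(pop["species"].iloc[0], a=0.05, b=-0.04, markov=markov)
proj = project_population(
    n0=float(pop["abundance"].iloc[0]),
    start_year=int(pop["year"].min()),
    params=params,
    config=SimulationConfig(
        n_sims=1000, end_year=int(pop["year"].max()),
        rng_seed=2, store_trajectories=True,
    ),
)
mean_r2, sd_r2 = r_squared_fit(pop, proj)
print(f"observed window {proj.start_year}-{proj.end_year}, "
      f"{len(pop)} censuses, 1000 replicates")
print(f"mean r-squared observed vs replicate abundances: {mean_r2:.2f} (SD {sd_r2:.2f})")
print("(share of observed abundance variance tracked by a single replicate)")

# episode lengths: observed flags vs a 3000-year simulation of the fitted chain
rng = np.random.default_rng(3)
d, sim = 0, []
for _ in range(3000):
    d = step_drought(d, markov, rng)
    sim.append(d > 0)
report = episode_length_check(run_lengths(flags), run_lengths(sim))
for state in ("drought", "nondrought"):
    o, s = report[state]["observed"], report[state]["simulated"]
    print(f"{state:>10} episodes: observed pseudomedian {o.pseudomedian:.1f} "
          f"[{o.lower:.1f}, {o.upper:.1f}] vs simulated {s.pseudomedian:.1f} "
          f"[{s.lower:.1f}, {s.upper:.1f}] -> "
          f"{'overlap' if report[state]['pass'] else 'NO overlap'}")
print("overall episode-length check:", "pass" if report["pass"] else "fail")
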