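"""Annual drought indices from a monthly drought-severity series.

Generates one synthetic location's monthly series, thresholds it at the
10th percentile, and prints the annual intensity indices, the episode
structure and the fitted Markov drought-generator parameters.
"""

import numpy as np

from droughtpop import (
    annual_indices_table,
    compute_threshold,
    estimate_markov_params,
    run_lengths,
)
from droughtpop.synthetic_data import SyntheticWorldSpec, generate_pdsi

spec = SyntheticWorldSpec(n_locations=1, start_year=1969, end_year=2005, seed=42)
series = generate_pdsi(spec)[0]

threshold = compute_threshold(series, percentile=10)
print(f"location {series.location_id}: theta = {threshold.theta:.3f} "
      f"(10th percentile of {threshold.n_reference_months} months)")

table = annual_indices_table(series)
print("\nfirst years (T = drought months, C = longest run, _t2 = two-year window):")
print(table.head(6).to_string(index=False))

flags = table.dropna(subset=["drought_year"])["drought_year"].astype(bool).tolist()
rl = run_lengths(flags)
print(f"\ndrought episodes (years): {rl.drought_run_lengths}")
print(f"non-drought episodes (years): {rl.nondrought_run_lengths}")
print(f"mean recurrence interval: {rl.mean_recurrence_interval:.2f} years "
      "(average distance between drought years)")

c_in_drought = table.loc[table["drought_year"] == True, "C"].astype(int).tolist()
markov = estimate_markov_params([flags], c_in_drought)
print(f"\nMarkov drought generator: P(drought year) = {markov.p_init:.2f}, "
      f"drought persistence ddt = {markov.ddt:.2f}, "
      f"non-drought persistence nddt = {markov.nddt:.2f}")
print("These three probabilities plus the C distribution drive the projection model.")
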