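"""Model-checking statistics for the stochastic projections.

Two checks mirror how the projection model is judged against observations:

* per-population r-squared between observed abundances and each simulated
  replicate's abundances at matching years, summarized as mean and SD over
  replicates (the SD captures between-replicate spread);
* Hodges-Lehmann pseudomedian point estimates with 95% confidence intervals
  (obtained by inverting the one-sample Wilcoxon signed-rank statistic) for
  observed and simulated drought / non-drought episode lengths, with a
  CI-overlap rule standing in for "well replicated".

The pseudomedian of a sample is the median of all Walsh averages
(x_i + x_j)/2 over pairs i <= j. The CI uses the exact null distribution of
the signed-rank statistic for n <= 25 and the normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .drought_indices import RunLengthStats
from .projection import PopulationProjection

__all__ = [
    "PseudomedianCI",
    "r_squared_fit",
    "pseudomedian_ci",
    "episode_length_check",
]


@dataclass(frozen=True)
class PseudomedianCI:
    pseudomedian: float
    lower: float
    upper: float
    confidence: float = 0.95
    n: int = 0

    def overlaps(self, other: "PseudomedianCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


def r_squared_fit(
    observed: pd.DataFrame, projection: PopulationProjection
) -> tuple[float, float]:
    """Mean and SD over replicates of r^2 (squared Pearson correlation)
    between observed abundances and replicate abundances at matching years.

    ``observed`` needs columns ``year`` and ``abundance``; the projection
    must have been run with ``store_trajectories=True``. r^2 discards the
    sign of the association (a perfectly declining replicate against an
    increasing observation also scores 1). Returns (nan, nan) when the
    observed series is constant (correlation undefined).
    """
    if projection.trajectories is None:
        raise ValueError("projection was run without store_trajectories")
    obs = observed.dropna(subset=["abundance"]).sort_values("year")
    years = projection.years
    mask = np.isin(obs["year"].to_numpy(), years)
    obs = obs[mask]
    if len(obs) < 3:
        raise ValueError(f"only {len(obs)} overlapping years, need >= 3")
    y = obs["abundance"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return float("nan"), float("nan")
    cols = np.searchsorted(years, obs["year"].to_numpy())
    sims = projection.trajectories[:, cols]  # (n_sims, n_years)

    yc = y - y.mean()
    sc = sims - sims.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ yc) / denom
    r2 = np.square(r[np.isfinite(r)])
    if len(r2) == 0:
        return float("nan"), float("nan")
    return float(r2.mean()), float(r2.std(ddof=1)) if len(r2) > 1 else 0.0


def _signed_rank_pmf(n: int) -> np.ndarray:
    """Null distribution of the Wilcoxon signed-rank statistic for sample
    size n: P(W = k) for k = 0..n(n+1)/2, by the generating-function
    recursion prod_i (1 + z^i) / 2^n."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for i in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[i:] = counts[:-i] if i <= max_w else 0.0
        counts = counts + shifted
    return counts / counts.sum()


def pseudomedian_ci(
    sample, confidence: float = 0.95, exact_max_n: int = 25
) -> PseudomedianCI:
    """Hodges-Lehmann pseudomedian with a signed-rank confidence interval.

    The point estimate is the median of all Walsh averages (x_i + x_j)/2,
    i <= j. The CI takes the qu-th smallest and qu-th largest Walsh average
    (1-based), with qu the alpha/2 quantile of the null signed-rank
    distribution — exact for n <= `exact_max_n`, the normal approximation
    (mean n(n+1)/4, variance n(n+1)(2n+1)/24) above; qu floors at 1.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 values, got {len(x)}")
    n = len(x)
    walsh = np.sort([(x[i] + x[j]) / 2.0 for i in range(n) for j in range(i, n)])
    point = float(np.median(walsh))
    alpha = 1.0 - confidence

    m = len(walsh)  # n(n+1)/2
    if n <= exact_max_n:
        cdf = np.cumsum(_signed_rank_pmf(n))
        qu = int(np.searchsorted(cdf, alpha / 2.0, side="left"))
    else:
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        qu = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma))
    qu = min(max(qu, 1), (m + 1) // 2)
    lo = walsh[qu - 1]
    hi = walsh[m - qu]
    return PseudomedianCI(point, float(lo), float(hi), confidence, n)


def episode_length_check(
    observed: RunLengthStats,
    simulated: RunLengthStats,
    confidence: float = 0.95,
) -> dict:
    """Compare observed vs simulated drought and non-drought episode lengths.

    Pseudomedian + CI for each of the four samples; each state passes when
    the observed and simulated intervals overlap.
    """
    out: dict = {}
    for state, obs_runs, sim_runs in (
        ("drought", observed.drought_run_lengths, simulated.drought_run_lengths),
        ("nondrought", observed.nondrought_run_lengths, simulated.nondrought_run_lengths),
    ):
        if len(obs_runs) == 0 or len(sim_runs) == 0:
            raise ValueError(f"empty {state} run sample")
        ci_obs = pseudomedian_ci(obs_runs, confidence)
        ci_sim = pseudomedian_ci(sim_runs, confidence)
        out[state] = {
            "observed": ci_obs,
            "simulated": ci_sim,
            "pass": ci_obs.overlaps(ci_sim),
        }
    out["pass"] = out["drought"]["pass"] and out["nondrought"]["pass"]
    return out
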