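# Methods

This note documents the models, conventions and design choices behind
`droughtpop`, in the order the pipeline runs.

## Drought classification and indices

Monthly drought-severity values `q` (standardized, negative = dry) are
classified per location against a threshold θ, the 10th percentile of the
location's own monthly reference distribution. Conventions:

- **Percentile.** Linear interpolation between closest order statistics
  (`numpy.percentile(..., method="linear")`); the percentile and the
  reference period are configurable (`compute_threshold`). The default
  reference distribution is every non-missing month of the series. At
  least 120 reference months are required (configurable floor) so the tail
  quantile is estimable.
- **Strictness.** A month is a drought month iff `q < θ`; ties at θ are
  non-drought.
- **Missing months** are excluded from threshold estimation, flagged
  non-drought for index computation, and counted; a year with more than 3
  missing months (configurable) yields absent indices rather than zeros.

Annual indices for calendar year `y`: `T` = number of drought months in
`y`; `C` = longest consecutive drought run within `y`; `T_t2`, `C_t2` = the
same over the 24 months of `{y−1, y}`, with runs allowed to cross the
December/January boundary (this is what distinguishes `C_t2` from
`max(C_{y−1}, C_y)`). A drought year is `T ≥ 1`. When year `y−1` is
unavailable the two-year indices are absent, not zero.

Annual summaries for correlation checks: the mean of the year's values,
and a mode defined on values rounded to one decimal with ties broken
toward the lower (drier) value — a raw mode of 12 continuous values would
be degenerate.

Populations are matched to gridded drought data by 2.5°×2.5° cells,
half-open and lower-edge inclusive with origin (−90, −180); the north pole
and the antimeridian clamp into the last cell.

## Growth rates and filters

`r_t = ln(N_{t+1}/N_t)` is computed only for censuses in consecutive
years; any gap of two or more years contributes nothing. Pairs containing
a zero abundance are skipped with a warning (the log is undefined) rather
than aborting a run. Filters, in pipeline order:

1. populations are dropped whole when their first census is below the
   species' herd-size range — compared against the range's lower bound by
   default (the most permissive reading; a midpoint option exists);
2. observations above the physiological ceiling
   `r_max = ln(1 + max offspring per female per year)` — an all-female,
   no-mortality population — are removed (one-sided: declines are kept);
3. species with 20 or fewer pooled observations are dropped (strictly
   more than 20 are required);
4. known managed/poached/multi-source populations are excluded via an
   explicit exclusion table; the package does not attempt to infer such
   metadata.

A growth observation for the interval `t → t+1` carries the drought
indices of calendar year `t` (drought during the interval's first year).
The alternative anchoring — the year before the interval — is one flag
away in `join_drought`, but the first-year convention is the default
because the census interval itself is when the drought acts on survival
and recruitment.

Life-history groups cross movement (sedentary S vs non-sedentary M) with
forage drought-tolerance (grazers and mixed feeders G vs browsers and
omnivores B).

## Mixed-effects drought response

Single-predictor models `r ~ D` for `D ∈ {C, T, C_t2, T_t2}` with crossed
random intercepts for population location and species, fitted by maximum
likelihood (not REML) so fits with different predictors are comparable.
Implementation: `statsmodels` MixedLM with one all-encompassing group and
two variance components. The p-value is a Wald z test on the slope. Groups
containing a single species drop the species component (its variance is
unidentifiable) with a log notice. Small variance components often sit on
the zero boundary, where gradient optimizers stall; the fit tries lbfgs,
bfgs, powell and nelder-mead in turn and raises with the optimizer trail
if none converges. Index choice for downstream projection is an explicit
configuration, defaulting to `C` (consecutive months capture episode
structure, matching standard definitions of a drought event).

## Projection model

Scalar geometric growth `N_{t+1} = N_t·exp(a + b·D_t)` with continuous
abundance (no demographic rounding, no density dependence, age structure,
predation or dispersal). `a` is the drought-free log growth rate:
by default the mean of observed `r_t` over drought-free observations
(`C = 0`), falling back to the overall mean with a warning when fewer than
5 drought-free observations exist. Alternatively `calibrate_intercept`
solves `a = ln(λ*) − b·E[mean D_t]` for a target mean λ, with
`E[mean D_t]` propagated analytically through the (possibly
scenario-modified) chain; the Jensen gap between `E[exp(mean R)]` and
`exp(E[mean R])` is below 10⁻⁴ at the drought variances involved, which
simulation checks confirm.

The drought generator is the two-state Markov chain (`p_init`, `ddt`,
`nddt`) plus the empirical distribution of within-year drought lengths
`C` (support 1–12 months). Per year: persistence draws first decide
drought/non-drought; drought years then draw a fresh length. The initial
year is drought with probability `p_init`.

Scenarios rescale the stationary drought-year frequency
`π = (1−nddt) / ((1−nddt) + (1−ddt))` to `π' = min(m·π, 0.95)` from the
onset year (step change: B1 doubles from 2025, A2 triples from 2040),
solving for the new entry probability `p_enter' = π'·(1−ddt)/(1−π')`
capped at 1. Drought persistence and the length distribution are left
unchanged: the scenarios are statements about how often droughts occur,
not how long they last. The 0.95 cap keeps the chain ergodic; when `ddt`
is small even `p_enter' = 1` cannot reach 0.95 and the entry probability
saturates instead. Medium-term droughts are assumed to scale like
short-term ones.

Monte-Carlo runs use 5000 replicates by default, each on an independent
seeded substream (`numpy` `SeedSequence.spawn`), so replicate `k` is
identical regardless of how many replicates are requested. A replicate is
absorbed as extinct the first year `N ≤ 5` individuals (threshold
configurable); abundance is held at the crossing value and growth stops
accumulating. Per replicate `λ_i = exp(mean R_t)` over the realized years
up to extinction or the horizon (2099); summaries are the mean and SD of
`λ_i` over replicates and `E`, the fraction extinct. Species-level
summaries are unweighted means across populations; the reported SD is the
across-replicate SD averaged over populations (alternatives — SD across
populations or years — are deliberate non-choices, flagged here).
Abundance is accumulated multiplicatively (`N *= exp(R)`), which keeps
exactly-representable declines exact and avoids drift from summing logs.

## Validation statistics

- **r².** Per replicate, the squared Pearson correlation between observed
  abundances and the replicate's trajectory at matching years; reported as
  mean and SD over replicates (hence against individual replicates, not
  the replicate mean). r² is affine-invariant and sign-blind — a perfectly
  anti-tracking replicate scores 1 — which is documented rather than
  patched. A constant observed series leaves r² undefined (NaN).
- **Episode lengths.** Hodges–Lehmann pseudomedian (median of all Walsh
  averages `(x_i+x_j)/2, i ≤ j`) with a 95% CI from inverting the
  one-sample Wilcoxon signed-rank statistic: exact null distribution
  (generating-function recursion) for n ≤ 25, normal approximation with
  mean `n(n+1)/4` and variance `n(n+1)(2n+1)/24` above; the rank index
  floors at 1. The convention matches R's `wilcox.test(conf.int=TRUE)`,
  which a unit test uses as an independent oracle. Observed-versus-
  simulated comparison uses a CI-overlap rule on two one-sample intervals
  — the statistically honest reading of a signed-rank check applied to
  unpaired run-length samples.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs, with
defaults chosen as the study conditions:

- **Monthly drought series**: stationary Gaussian AR(1),
  `q_t = φ·q_{t−1} + ε_t`, initialized from the stationary marginal.
  φ = 0.88 (monthly persistence) was calibrated once so that
  10th-percentile thresholding yields drought/non-drought year episodes
  with pseudomedians ≈ 2 and ≈ 3 years — the episode structure typical of
  the semi-arid African study systems; the innovation SD (1.0) only sets
  the scale and cancels in thresholding. Grid cells are independent: no
  spatial correlation is emulated.
- **Abundance records**: log-abundance random walk with drift
  `a + b·C_year + u_location + v_species`, log-normal observation noise
  (SD 0.05 — survey CVs of a few percent, multiplicative because
  abundances are positive), random-intercept SDs 0.02, censuses dropped
  independently with probability 0.1 (irregular surveys; both ends of a
  pair must survive for a growth observation), initial abundances uniform
  on 200–2000, study years 1970–2005 with a 1969 spin-up year so two-year
  indices exist from the start. True `a` = 0.05/yr and `b` = −0.04 per
  drought month by default.
- **Traits**: a fixed table covering all four life-history groups, herd
  sizes 10–50 and one offspring per female per year (ceiling ln 2),
  plausible for medium-sized ungulates.

What passing on synthetic data does *not* show: robustness to spatially
correlated drought, to non-AR(1) climate persistence, to density
dependence or demographic structure in the populations, or to census
errors that are not independent log-normal. The differenced observation
noise also makes consecutive growth rates weakly negatively correlated
(MA(1)), which the mixed model ignores — as it would on real data.

## Problem sizes

Default test and acceptance runs use 5000 Monte-Carlo replicates for
projections (the study's own replicate count), 10⁵ simulated years for
stationary-frequency checks, 200 synthetic studies of ~150 observations
for slope-recovery coverage, and 12 000-month series for threshold
calibration — sizes at which the Monte-Carlo error is comfortably inside
each check's tolerance.

## Known limitations

- The Wald z p-value ignores small-sample degrees-of-freedom corrections;
  with few locations/species it is mildly liberal.
- The scenario rescaling holds `ddt` fixed, so extreme multipliers are
  frequency-capped rather than faithfully tripled for already-droughty
  chains (logged above).
- λ for replicates that go extinct early averages `R_t` over few years and
  is therefore noisy; it is reported as-is.
- The exclusion of managed/poached populations is input metadata; nothing
  is inferred from the records themselves.
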