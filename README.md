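# droughtpop

Population viability analysis of ungulates under increasing drought.

Herbivore populations in arid and semi-arid environments are strongly
limited by resource availability, and droughts — rare, extended runs of dry
months — can drive their numbers down sharply. `droughtpop` implements a
complete pipeline for quantifying that link and projecting its consequences
under climate-change scenarios: it derives annual drought-intensity indices
from monthly drought-severity series (Palmer-type, standardized −10 dry to
+10 wet), estimates how yearly population growth rates respond to drought
with mixed-effects regressions, and feeds the fitted response into a
stochastic Markov-drought population model that projects abundance and
extinction risk to 2099. It is written for quantitative ecologists working
with Living-Planet-Index-style census data and gridded climate indices.

## The model

A year is a *drought year* at a location when at least one month's
drought-severity value `q` falls strictly below the threshold θ, the 10th
percentile of the location's monthly reference distribution. Four annual
intensity indices count sub-threshold months: `T` (total, current year),
`C` (longest consecutive run, current year), and `T_t2`, `C_t2` over the
two-year window ending in the current year.

Observed growth rates are `r_t = ln(N_{t+1}/N_t)` from consecutive-year
censuses. The drought response is the slope `b` of the linear mixed model

    r_t = a + b·C + u_location + v_species + ε,

fitted by maximum likelihood with crossed random intercepts, pooled and per
life-history group (sedentary/mobile × grazer-mixed/browser-omnivore:
SG, SB, MG, MB).

The projection model is geometric growth forced by a two-state Markov
drought generator:

    N_{t+1} = N_t · e^{R_t},   R_t = a + b·D_t,

where `D_t` is the number of drought months in year `t`: a drought year
follows a drought year with probability `ddt`, a non-drought year follows a
non-drought year with probability `nddt`, and drought years draw `D_t` from
the empirical distribution of `C` (1–12 months). Scenario 20C keeps these
probabilities; B1 doubles the stationary drought-year frequency from 2025
and A2 triples it from 2040 (acting on the entry probability `1 − nddt`,
capped at a frequency of 0.95). A Monte-Carlo run (5000 replicates to 2099)
reports λ — the mean over replicates of the per-replicate geometric-mean
annual growth `exp(mean R_t)` — and the extinction probability `E`, the
fraction of replicates at or below 5 individuals by the horizon.

Because real LPI abundance records are confidential, the package ships a
synthetic-data generator with the same statistical structure (AR(1) monthly
drought series; abundance random walks with known `a`, `b`, random
intercepts, observation noise, and irregular census gaps), so every stage
runs and is validated end to end with known ground truth.

## Worked example

`examples/04_projection_scenarios.py` projects a declining
(waterbuck-like, λ = 0.92) and a growing (buffalo-like, λ = 1.05)
population of 1000 individuals from 1970 under all three scenarios:

```
population            scenario  lambda (SD)              E
waterbuck-like        20C       0.919 (0.011)     1.0000
waterbuck-like        B1        0.915 (0.008)     1.0000
waterbuck-like        A2        0.918 (0.010)     1.0000
buffalo-like          20C       1.050 (0.009)     0.0000
buffalo-like          B1        1.025 (0.007)     0.0000
buffalo-like          A2        1.030 (0.007)     0.0000
```

A population shrinking ~8% per year is certain to fall below 5 individuals
before 2099 (E = 1) whatever the scenario; a growing one essentially never
does, though worsening drought trims its growth rate. The other example
scripts walk through index computation (`01`), growth-rate filtering
(`02`), the mixed-model fit — recovering a known slope b = −0.04 with its
95% CI (`03`) — and model checking with r² and episode-length pseudomedians
(`05`). A thin CLI mirrors the same stages
(`droughtpop synth | indices | growth | fit | simulate | validate`).

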