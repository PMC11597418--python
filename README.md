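# paddyn

Simulation toolkit for **nitrogen runoff loss from flooded rice paddies**
under green-manure fertilizer substitution.

Winter green manure (Chinese milk vetch, a legume) lets rice growers cut
mineral nitrogen fertilizer by ~40% without losing yield — but how much
nitrogen that keeps out of surface waters, and how the answer depends on
whether a year is wet or dry, is hard to measure: it takes multi-year,
multi-site monitoring. `paddyn` is a process-lite simulation pipeline for
exactly that question, aimed at agro-environmental modellers: a daily
ponding-water balance with threshold runoff and managed drainage, lumped
surface-water nitrogen pools with runoff-loss accounting, trial-and-error
calibration scored by RMSE / index of agreement / Nash–Sutcliffe efficiency,
a stochastic weather generator, and a 50-year scenario engine comparing four
field treatments:

| code | treatment |
|------|-----------|
| FR   | conventional mineral fertilization |
| FRS  | conventional + rice-straw return |
| MR   | green manure, mineral N cut 40% |
| MRS  | green manure + straw, mineral N cut 40% |

## The model

**Water.** End-of-day ponding depth follows the daily balance

    Pd_n = Pd_{n-1} + Prem_n + Irri_n − ET_n − Inf_n − Rf_n        (mm)

with threshold runoff `Rf = max(0, Pd − Pd_max)` at the bund height, plus
managed drainage: a storm-control release back to the target depth and
forced dry-downs at late tillering and pre-harvest. ET is Hargreaves–Samani
(or a supplied ET₀ column) times a crop coefficient; infiltration is a
constant percolation rate under ponding.

**Nitrogen.** The flood water carries four per-area pools (kg N ha⁻¹):
NH₄⁺-N, NO₃⁻-N, dissolved organic N and particulate N, related by the
difference method DIN = NH₄ + NO₃, DTN = DIN + DON, TN = DTN + PN, with
concentration (mg L⁻¹) = 100 · mass / depth. Each pool decays by an exact
daily exponential at a lumped first-order rate; a fraction of broadcast
fertilizer N enters the NH₄ pool directly, the rest joins a puddled-layer
soil store that slowly exchanges back into the flood water while the crop
draws it down. Green manure and straw mineralize first-order; straw
additionally immobilizes NH₄ while it decomposes. Every runoff or drainage
event exports

    Q = Σ_i C_i · Rf_i · 10⁻²        (kg N ha⁻¹)

at the day's fully-mixed concentration, and the seasonal budget closes to
machine precision because concentrations are derived from masses, never
integrated.

**Evaluation and calibration.** Model fit is scored by RMSE, the index of
agreement d ∈ [0, 1] and Nash–Sutcliffe efficiency E ≤ 1; calibration is a
deterministic staged grid descent (percolation rate on depth/runoff series,
then N parameters on log-scale concentrations) that mirrors manual
trial-and-error tuning.

**Weather and year types.** Daily precipitation is a monthly two-state
first-order Markov chain (wet/dry occurrence) with Gamma-distributed wet-day
amounts, fitted per calendar month and sampled reproducibly. Years are
classified by the drought index DI = (P − A)/σ of growing-season rainfall:
wet if DI > 0.35, dry if DI < −0.35, normal between.

No field observations ship with the package: a synthetic-data module
generates site configurations (management facts — N rates, 6:4 / 11:7:2 /
7:2:1 splits, season dates — follow four published Yangtze-basin stations),
hidden truth parameters, and noisy observations on the real monitoring
schedule (day 0 before each fertilization, then days 1, 3, 5, 7, 10 after).

## Worked example

`examples/` holds one short script per capability. The scenario comparison
(`python examples/05_scenarios.py`) generates 50 years of weather, runs all
four treatments on the same years, stratifies by drought index and prints:

```
mean seasonal TN loss (kg N/ha) by year type and treatment:
                  FR     FRS      MR     MRS
wet    n=21     8.85    8.30    7.84    7.48
normal n=9      8.27    7.86    7.15    6.87
dry    n=20     6.38    6.06    5.72    5.51

reductions vs FR (paired year-level bootstrap (Holm-corrected), alpha=0.05):
  wet    MR   TN - 11.4%   DIN - 17.5%*
  wet    MRS  TN - 15.5%   DIN - 26.6%*
  normal MR   TN - 13.4%   DIN - 19.2%*
  normal MRS  TN - 16.8%   DIN - 26.7%*
  dry    MR   TN - 10.4%   DIN - 15.9%*
  dry    MRS  TN - 13.7%   DIN - 24.1%*
```

Losses order FR > FRS > MR > MRS within every year type and wet > normal >
dry within every treatment; the green-manure treatments cut dissolved
inorganic N hardest (a `*` marks Holm-corrected p < 0.05). The calibration
example (`examples/04_calibration.py`) recovers the hidden percolation rate,
NH₄ removal rate and fertilizer surface fraction from noisy observations to
within a few percent, with d and E above 0.97 on all four series.

A thin CLI wraps the same functions:

```sh
paddyn weather generate --years 50 --seed 1 --out weather.csv
paddyn weather fit weather.csv
paddyn weather classify weather.csv
paddyn synth --profile nanjing --seed 1 --out site/
paddyn calibrate --profile default --seed 1
paddyn scenario --profile default --years 50 --seed 1 --out run/
```

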