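# Methods

This note documents the models inside `paddyn`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a user recalibrating the package should know about.

## Ponding-water balance

The field is a single bunded water store with daily bookkeeping

Pd_n = Pd_{n−1} + Prem_n + Irri_n − ET_n − Inf_n − Rf_n  (all mm),

applied within a day in the order precipitation → irrigation → ET →
infiltration → runoff, so that management reacts to same-day rain. The
order matters — runoff totals differ under permutations — and is therefore
fixed and documented rather than configurable. ET and infiltration are
capped at the available water, so depth never goes negative; the daily and
seasonal budgets then close identically (tested to 10⁻⁹ mm).

Runoff has two components, reported separately and summed:

* **bund overflow** `max(0, Pd − Pd_max)`, with `Pd_max = 250 mm` (the top
  of the observed management envelope);
* **managed drainage** — forced dry-downs during the late-tillering
  (days 40–46 after transplanting) and pre-harvest (last 10 days) windows,
  during which irrigation is suppressed and the field drains to zero; and a
  storm-control release: when the end-of-day depth exceeds `pd_upper`
  (80 mm at the synthetic sites) the farmer drains back to the 60 mm
  target. Without the storm control, overflow at a 250 mm bund essentially
  never occurs and simulated seasons lose three orders of magnitude less N
  than monitored paddies; active drainage is also what field studies report
  as the dominant runoff pathway, especially in dry years.

Irrigation tops the field up to `pd_target = 60 mm` whenever the
start-of-day depth falls below the trigger. The generic default trigger is
20 mm; the synthetic sites use 40 mm so the monitored depth stays at
35–60 mm through the fertilization weeks. At a 20 mm trigger the
between-irrigation drawdown (≈13 mm day⁻¹ of ET + percolation) concentrates
the flood water faster than NH₄ decays and the sampled concentration peak
drifts off day 1, which contradicts the observed structure the synthetic
data must reproduce.

Reference ET is the supplied `et0` column when present, otherwise
Hargreaves–Samani 0.0023 · Ra · (Tmean + 17.8) · √(Tmax − Tmin) from
latitude and day of year; actual ET is kc · ET₀ with kc = 1.05 by default.
Full Penman–Monteith needs humidity and wind that daily station tables
lack. Infiltration under ponding is a constant percolation rate
(unit-gradient saturated flow); it is the principal hydraulic calibration
parameter, drawn from 5–10 mm day⁻¹ at the synthetic sites.

## Surface-water nitrogen

Four per-area pools (kg N ha⁻¹) ride on the flood water: NH₄⁺-N, NO₃⁻-N,
dissolved organic N (DON) and particulate N (PN). Concentration is always
derived as 100 · mass / depth (mg L⁻¹, depth in mm), never integrated, so
dilution by rain and concentration by ET are exact and the difference-method
identities TN = DTN + PN, DTN = DIN + DON, DIN = NH₄ + NO₃ hold at every
step by construction.

Each pool decays by an exact daily exponential with a lumped first-order
rate: `k_nh4` (volatilization + nitrification + uptake + adsorption,
default 0.30 day⁻¹, drawn 0.25–0.40 at the synthetic sites), `k_no3`
(denitrification + uptake + leaching, 0.70), `k_don` (decomposition, 0.15),
`k_pn` (settling, 0.20). A fraction `nitrif_frac = 0.04` of NH₄ removal is
credited to the NO₃ pool. The NO₃ parameters are set high/low respectively
because ponded flood water is largely anaerobic: nitrification is weak, and
these values keep NH₄/DIN above 0.9 during fertilization weeks, as field
monitoring consistently reports.

**Inputs.** Broadcast urea is assumed hydrolyzed within the daily step; a
fraction `f_surf = 0.3` of each application enters the surface NH₄ pool and
the remainder joins a puddled-layer soil store. Organic inputs (green
manure, straw) mineralize first-order (`n · k_min · e^{−k_min t}`); of each
day's release a small fraction (`f_surf`: 0.05 GM, 0.03 straw) reaches the
surface pools split 60:40 NH₄:DON, a fraction `f_soil` (0.6 GM, 0.3 straw)
joins the soil store, and the rest is treated as stabilized into soil
organic matter. Incorporation adds a one-time PN pulse (2% GM, 1% straw of
N content). Straw, being high-C:N, additionally immobilizes surface NH₄ at
`k_imm · e^{−k_min t}` with `k_imm = 0.08 day⁻¹` — this is what makes straw
return *lower* dissolved N losses despite adding N, reproducing the
FR > FRS contrast.

**Soil–water exchange.** The soil store returns N to the flood water at
`k_soil` (0.008 day⁻¹ at the synthetic sites; split 70:30 NH₄:DON) while
crop uptake drains it at `k_up = 0.04 day⁻¹`; soil organic matter
mineralization feeds the store at `soil_min_rate` (2.0 kg N ha⁻¹ day⁻¹ at
the synthetic sites, 0 by default so a zero-input season loses exactly
zero N). This sustains the observed 2–4 mg L⁻¹ background TN between
fertilizer pulses. The background matters structurally: it ties seasonal
losses to runoff volume (hence to season rainfall), which is what makes
wet > normal > dry mean losses emerge, and it is why dry-year treatment
differences are small — in dry years most export is drainage at background
concentration, which the treatments share.

**Runoff export** removes the fully-mixed fraction rf/(pd + rf) of every
pool at the day's pre-runoff concentration; the per-event loss is
C_i · Rf · 10⁻² kg N ha⁻¹ and the seasonal total is the sum over events.
The seasonal N budget (inputs − decay − export − Δstorage) closes to
10⁻⁹ kg N ha⁻¹ by construction and is asserted in the tests.

## Evaluation metrics and calibration

RMSE, Nash–Sutcliffe efficiency E = 1 − Σ(O−P)²/Σ(O−O̅)², and the index of
agreement d = 1 − Σ(O−P)²/Σ(|P−O̅| + |O−O̅|)² are implemented directly;
constant observation series raise rather than returning sentinels, since
E and d are undefined there.

Calibration operationalizes manual trial-and-error as a deterministic
pattern search: each round sweeps every parameter over a grid inside its
current bracket, keeps improvements, and shrinks the bracket only when a
full sweep moves nothing. The stall-based refinement is essential: on the
correlated decay-rate / surface-fraction ridge a fixed shrink schedule
converges prematurely. The search is staged the way paddy models are tuned
in practice: the percolation rate is fitted first against ponding-depth and
runoff series (a rugged, day-discontinuous response — shifting one
irrigation day jumps the error — hence a dense 61-point grid), then the N
parameters against concentration series on a log1p scale (appropriate for
multiplicative sampling noise), where the surface is smooth. The objective
is the mean over series of RMSE normalized by the observed standard
deviation. Failed candidate simulations are logged and scored +∞, never
fatal. With 5% observation noise the staged search recovers the three
default parameters within a few percent (worst observed across seed sweeps:
~6%).

## Weather generator and year classification

Wet/dry occurrence is a two-state first-order Markov chain with monthly
transition probabilities; wet-day precipitation is the wet threshold
(0.1 mm) plus a Gamma(shape, scale) excess, fitted per month by the method
of moments (MLE optional). Months with fewer than five wet days fall back
to the pooled annual fit and are flagged. Temperatures are monthly normals
with a truncated diurnal range so tmax ≥ tmin always — deliberately minimal
plumbing, since only ET consumes them.

Fitting tolerances: at 10 years of record the *typical* monthly
transition-probability error is ±0.03 and the worst of the 24 monthly
estimates is ~±0.12 (binomial noise on ~180 pairs/month); at 200 years the
worst month is within ±0.05 (probabilities) and ±10% (mean wet-day amount).
Tests assert exactly these, with the 10-year worst-month envelope derived
by Monte Carlo before freezing.

Years are labelled by the drought index DI = (P − A)/σ where P is
growing-season rainfall (transplant→harvest; calendar-year window
available) and A, σ are the mean and sample standard deviation of the same
generated set — the classification is deliberately self-referential, not
anchored to an external climatology. Thresholds: wet iff DI > 0.35, dry iff
DI < −0.35, boundaries inclusive into normal.

The built-in climate is a humid-subtropical monsoon (annual ≈ 1500 mm,
summer-dominant, heavy-tailed convective storms — July Gamma scale 26 mm),
consistent with the 1100–1620 mm annual range of the four reference
stations.

## Scenario analysis

All treatments share each year's weather realization (a paired design), so
treatment contrasts are within-year. FR/FRS carry the full mineral N rate;
MR/MRS carry 60% of it plus a 60 kg N ha⁻¹ milk-vetch input incorporated
10 days before transplanting; FRS/MRS add a 30 kg N ha⁻¹ straw return at
the same time. Summaries report mean ± sd of seasonal TN and DIN loss per
(treatment, year type), with percent reductions against a declared baseline
and significance from a seeded year-level bootstrap of paired differences
with Holm correction (the procedure name is carried in every summary). The
winter-fallow baseline of the four-treatment design maps to FR/FRS (no
green manure).

With 50-year samples and storm-dominated loss distributions the
within-treatment year-type means carry real sampling noise: the
FR > FRS > MR > MRS ordering is robust across weather realizations, while
normal-vs-dry mean flips occur at a minority of seeds. This is genuine
stochastic variability, not a model defect; ordering-violation counts are
reported, never suppressed.

## Synthetic data: what it does and does not show

The generator is the simulator plus mean-preserving multiplicative
lognormal noise (5% depth, 10% concentrations and runoff by default),
sampled on the field monitoring schedule: day 0 immediately before each
fertilization, then days 1, 3, 5, 7, 10 after. Management facts for the
named site profiles — seasonal N rate, basal:tillering(:booting) split,
transplant/harvest dates, latitude — follow the four published stations
(including the double-cropping profile, generated as two independent
seasons with no carryover); soil hydraulic and N-rate truths are drawn
reproducibly from documented plausible ranges.

Passing tests on these data show the pipeline is internally consistent —
conservation, identifiability of the calibrated parameters under the stated
noise, and the qualitative treatment/year-type structure. They do not show
that the lumped rates transfer to any real site: real paddies have soil-N
profiles, sediment dynamics, analyzer-specific measurement error and
management deviations the generator deliberately omits. PN dynamics in
particular are a minimal settling model; conventional-only treatments carry
no particulate load.

## Numerical choices and limitations

* Exact exponential decay steps; no ODE solver, no step-size error.
* Fertilization on a dry field is deferred to the first ponded day with a
  logged warning.
* At zero ponding depth concentrations are reported as 0 while masses are
  retained in the field.
* Problem sizes in tests and the acceptance script (single seasons,
  50-year scenarios, 200-year generator recovery, ~600-run calibrations)
  were chosen so each check completes in seconds while keeping sampling
  error well inside the asserted tolerances.
* Out of scope by design: soil-profile water/N transport (Richards,
  Green-Ampt, convection–dispersion), crop growth and yield, gaseous N
  partitioning, sub-daily routing, multi-site meta-analysis.
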