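# Methods

## The cultivation-economics model

`greenprofit` evaluates a dwarf-tomato greenhouse cultivation — transplant
to a single final harvest — against the economic objective used in
autonomous-greenhouse competition trials: the average daily net profit per
m² of greenhouse,

    net profit = (G − Σ_d (F + V_d) · a_d) / Σ_d a_d        [EUR/m²/day]

with d = 1…D the days since transplanting, D the harvest day, G the gains
per pot at harvest, F the daily fixed costs, V_d = L_d + H_d + C_d the
daily variable costs (all EUR/m²/day), and a_d = 1/δ_d the area one pot
occupies under plant density δ_d (pots/m²). The net profit per pot is
computed first and then divided by the accumulated pot-area-days.
Equivalently, net profit = (G − cost per pot) · δ̄ / D, where
δ̄ = D / Σ a_d is the (harmonic-type) average density; this identity is
enforced by a property test. The harvest day D accrues area and fixed
costs like any other day.

### Cost components

All component formulas operate on 5-minute actuator records (12 per hour,
288 per civil day).

* **Lamp electricity.** Dimming is linear: a record at activation p %
  draws `p/100 · I_max / η` W/m², with `I_max = 200` µmol/(m² s) the full
  installation and `η = 3.2` µmol/J the lamp efficacy, so one record at
  100 % contributes 62.5/1000/12 ≈ 0.00521 kWh/m². Each record is priced
  by the tariff of its *start* instant: 0.30 EUR/kWh on-peak
  (Monday–Friday, 07:00 inclusive to 23:00 exclusive, local clock),
  0.20 EUR/kWh otherwise, weekends entirely off-peak. The calendar is
  daylight-saving aware (default timezone Europe/Amsterdam).
* **Heating.** A pipe-rail delivers approximately
  `P = 2 · max(0, T_pipe − T_air)` W/m². Pipe temperatures are only
  meaningful while the circulation pump runs; with the pump off (or the
  pipe channel absent) the delivered power is zero. Daily energy is
  `E_H = Σ P/1000/12` kWh/m², priced at 0.09 EUR/kWh.
* **CO2.** The platform records a *cumulative dosing-duration* counter in
  minutes. Each positive per-record increment × 0.125 g/(m² min) gives the
  dosed mass, priced at 0.30 EUR/kg. Counter decreases (resets) contribute
  nothing, which also makes the daily cost invariant to how dosing is
  distributed within a day as long as the counter's daily endpoints agree.
* **Fixed costs.** `F = 18.1250/365 + 0.07/365 · I_inst + 1.50/365 · n_s`
  EUR/m²/day: greenhouse upkeep (≈0.05), lamp depreciation scaled by the
  installed intensity `I_inst` (µmol/(m² s)) and a charge per spacing
  change `n_s` (0–3). `I_inst` is inferred as the trace's *peak* lamp
  activation × 200 unless given explicitly.

### Gains and the price model

At harvest a pot is priced from the red (ripe) fruit fresh weight ffw
(g/pot), the red-fruit dry-matter percentage dmp, and the ripe fraction
rfp. Gates: rfp < 1/3 or ffw < 50 g → unsellable, P = 0 (rfp values
slightly above 1, an artifact of measuring different plants, are clamped
to 1 for gating). Above the gates, the price at the 150 g weight cap
interpolates linearly in dmp between a low curve (dmp ≤ 7 %, 1.80 EUR)
and a high curve (dmp ≥ 8 %, 2.00 EUR). Above the cap the price is flat.
Gains per pot are G = P − 0.75 (plant cost); an optional intervention
penalty of 0.10 EUR/pot per manual intervention exists but is disabled by
default.

Two deliberate choices where the published material is graphical or
silent:

* **Cap prices.** The curve endpoints are published only as a figure. The
  defaults (1.80, 2.00) are obtained by `calibrate_price_caps`, a linear
  least-squares inversion of the six-team results table (every team
  harvested above the weight cap, so gains + 0.75 = (1−w)·low + w·high
  with w the clamped dmp interpolation weight). The fit is exact to
  machine precision; the caps are config-overridable.
* **Sub-cap shape.** No trial result fell between 50 g and 150 g, so the
  weight dependence below the cap is unconstrained by data. Default:
  price proportional to ffw/150 (linear through the origin, gated at
  50 g); a `flat` variant is provided. This choice cannot affect the
  published-table reproductions.

### Harvest-date optimization

The retrospective question "when should this compartment have harvested?"
is answered by an exhaustive scan. Red fruit weight and ripe fraction are
linearly interpolated to daily resolution between the sparse destructive
measurements (no extrapolation); dmp is frozen at its final observed
value; the realized cost trajectory and density schedule are kept, and
costs after a hypothetical earlier harvest are simply not incurred. The
candidate window is the observed span capped at the actual harvest day.
For each candidate D′ the net profit is recomputed with the objective
truncated at D′; the spacing-change charge counts only changes realized
on or before D′. Ties go to the earliest day (shorter cycles permit more
cycles per year). The returned optimum is checked against an independent
brute-force re-scan in the tests. A window that never clears the
sellability gates still returns the least-negative day, flagged.

### Derived metrics

* **Annualized yield** = red_ffw · δ̄ / D · 365 / 1000 kg/m²/year.
* **Light-use efficiency** = grams of fruit fresh weight per m² per mol of
  total PAR (natural + artificial). Implemented strictly by definition;
  the package does not attempt to reconstruct PAR sums from actuator
  records, so LUE is only populated when a PAR total is supplied.

## Synthetic data

The generator emulates the *statistical structure* the pipeline consumes,
not greenhouse physics:

* **Traces** — lamp activation as photoperiod-gated Gaussian dimming noise
  (mean 60 %, sd 5 %, clipped to a per-scenario ceiling) over a 16 h
  default photoperiod; day/night square-wave air temperature
  (21.5/19.0 °C ± 0.3) ; a night heating window in which the pipe runs
  ~10 °C above air with the pump on; a cumulative CO2 counter advancing
  120 min/day across a daytime dosing window. Timestamps are genuine
  Europe/Amsterdam local time from a September transplant, so long runs
  include the 25-hour clocks-back day, which the validators and tariff
  calendar must (and do) handle.
* **Crop series** — total fruit weight follows a logistic
  K/(1+exp(−r(t−t0))) (defaults K = 280 g/pot, r = 0.12 /day, t0 = 45 d);
  the ripe fraction follows a delayed, steeper logistic; red weight is
  their product. Observations default to the trial's cadence (days 34,
  49, 63 and harvest) with 5 g Gaussian weight noise. The logistic forms
  are this package's own modelling choice — the trial publishes no growth
  equations — with parameters chosen to saturate at 250–300 g/pot by day
  70–80 and reach ≥75 % ripeness at harvest, matching the published
  outcome ranges.
* **Benchmark suite** — six scenario templates spanning spacing
  strategies from one very early change down to 20 pots/m² through three
  staged changes with late re-spacing, photoperiods 13–18 h and dimming
  ceilings 75–100 %. Average densities span ≈23–39 pots/m², the observed
  trial range. A schedule with *zero* changes would sit at the mandated
  56 pots/m² start density for the whole run, outside that range, so the
  default suite uses 1–3 changes. Each bundle can retain a ground-truth
  ledger computed by a deliberately naive per-record Python loop, kept
  independent of the vectorized accounting path.

What the generator does **not** emulate: weather and natural light,
screen/ventilation dynamics, humidity and irrigation channels, sensor
dropouts and delays (the reader's gap-filling is tested on synthetically
punctured CSVs instead), within-compartment plant-to-plant variance
beyond one additive noise term, and the fruit-drop artifact sometimes
seen at final harvests. Passing tests therefore demonstrate the
correctness of the accounting, pricing and optimization logic under
realistic magnitudes — not climate realism.

All randomness flows from one root seed through named
`numpy.random.SeedSequence` spawns (lamp/air/pipe/crop), so traces and
crop series regenerate independently and byte-identically.

## Numerical and I/O choices

* A cultivation day is a local-clock midnight-to-midnight window; day 1 is
  the transplant day. Validation requires every covered local date to be
  complete at the 300 s step (288 records, or 276/300 on daylight-saving
  days).
* Reader gap policy: up to 6 consecutive missing records (30 min) are
  filled — last observation carried forward for state channels, linear
  interpolation for the cumulative CO2 counter (preserving monotonicity) —
  with a logged warning; longer gaps are an error.
* Internal arithmetic never rounds; human-readable summaries round money
  half-up to 2 decimals (`decimal`), machine JSON keeps full precision and
  round-trips exactly.
* Calibration uses `numpy.linalg.lstsq` after an explicit rank check;
  an all-low-dm (or all-high-dm) table is rejected as underdetermined.
* Ranking sorts by net profit descending with ties broken by lower cost
  per pot (stable mergesort).
* Logistic refits use `scipy.optimize.curve_fit` seeded at
  (1.05·max, 0.1, median day). The packaged recovery experiment samples
  daily over days 15–80: three logistic parameters are not identifiable
  from the trial's four-date cadence at 5 g noise, so the experiment uses
  the denser design.

## Problem sizes

Tests and the acceptance checks run on: a hand-computable 3-day toy trace;
2–10-day randomized traces for oracle equivalence; 20 simulated 70–80-day
compartments (≈0.4 M records total) for the full-trace vs summary-path
agreement; 50 random trajectories for the optimizer re-scan; and the
published six-row trial table for all printed-value reproductions. The
whole suite completes in a few seconds.

## Known limitations

* The tariff calendar knows weekday/weekend and clock-time windows only —
  no public holidays or variable (spot) electricity prices.
* Heating accounting trusts the reported pump state; a stuck sensor would
  silently zero (or inflate) heat costs.
* The summary evaluation path treats published average density as exact;
  printed-table reproductions inherit the table's 2–3-significant-figure
  rounding.
* Light-use efficiency requires an externally supplied PAR total.
* The harvest optimizer freezes dmp at the final observation; if dry
  matter drifted materially during the last weeks, the retrospective
  profits at early candidate days are approximate.
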