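# greenprofit

Cultivation economics for autonomous greenhouse **dwarf tomato**: cost
accounting over 5-minute actuator traces, fruit-value pricing, the
net-profit objective over a plant-density schedule, retrospective
harvest-date optimization, and a seeded synthetic-data generator.

Dwarf cherry tomato is grown in pots at stepwise-decreasing density
(56 → 42 → 30 → 20 pots/m²) and harvested in a single instance, which
makes it a natural testbed for fully autonomous greenhouse control: an
algorithm chooses lighting, heating, CO2 dosing, spacing moments and the
harvest day, and is scored on the average daily net profit per m² of
greenhouse. This package implements that scoring pipeline — the same
computation used to rank control algorithms in autonomous-greenhouse
competition trials — as a tested, reusable library for researchers
evaluating cultivation strategies.

## The objective

    net profit = (G − Σ_d (F + V_d) · a_d) / Σ_d a_d     [EUR/m²/day]

* d = 1…D days since transplanting, D the chosen harvest day;
* a_d = 1/δ_d the area one pot occupies under plant density δ_d;
* F daily fixed costs: 18.1250/365 + 0.07/365·I_inst + 1.50/365·n_spacings
  (greenhouse upkeep, lamp depreciation at installed intensity I_inst
  µmol/(m² s), spacing-change charges);
* V_d = L_d + H_d + C_d daily variable costs from the 5-minute records:
  lamp electricity (linear dimming, 200 µmol/(m² s) at 3.2 µmol/J, dual
  tariff 0.30/0.20 EUR/kWh with on-peak Mon–Fri 07:00–23:00 local time),
  pipe-rail heating (2·max(0, T_pipe − T_air) W/m² while the pump runs,
  0.09 EUR/kWh) and CO2 dosing (0.125 g/(m² min) of counted dosing time,
  0.30 EUR/kg);
* G = P − 0.75 gains per pot, where the price P depends on the red fruit
  fresh weight (≥50 g to sell, flat above 150 g), the ripe fraction
  (≥1/3 to sell) and the fruit dry-matter percentage (linear interpolation
  between a low-price curve at ≤7 % and a high-price curve at ≥8 %).

See `docs/methods.md` for the full model description, assumptions and
design choices.

## Worked example

Simulate a 70-day compartment, evaluate it, and ask when it should have
harvested:

```sh
$ greenprofit simulate --seed 7 --duration 70 --out demo/
wrote trace/schedule/observations to demo (seed=7)

$ greenprofit evaluate --trace demo/trace.csv --schedule demo/schedule.csv \
      --obs demo/observations.csv --team demo --out demo/eval
net profit: 0.2683 EUR/m²/day (reports in demo/eval)

$ greenprofit optimize-harvest --obs demo/observations.csv \
      --ledger demo/eval/ledger.csv --schedule demo/schedule.csv \
      --duration 70 --intensity 200
11 d earlier: 0.26 → 0.47, +0.21 (+82%)
```

The evaluation writes a per-day cost ledger (`ledger.csv`: lamp kWh and
EUR, heating kWh and EUR, CO2 kg and EUR, fixed costs, pot area) and a
summary; 0.2683 EUR/m²/day is the realized objective for this simulated
strategy. The optimizer interpolates the sparse crop measurements to
daily resolution and re-runs the objective truncated at every candidate
day: here, harvesting 11 days earlier would have nearly doubled the
profit — the crop had saturated while daily costs kept accruing.

Ranking the published six-team trial summaries and re-deriving the price
curve's unpublished cap prices from them:

```sh
$ greenprofit rank
 rank       team  net_profit  gains_per_pot  cost_per_pot  duration_days  avg_density
    1      IDEAS    0.345957           1.05          0.44             70         39.7
    2     MuGrow    0.174957           1.11          0.74             70         33.1
    3    Trigger    0.133600           1.05          0.73             80         33.4
    4  Reference    0.129919           1.05          0.67             74         25.3
    5 Agrifusion    0.118590           1.09          0.72             78         25.0
    6 Tomatonuts    0.040250           1.05          0.91             80         23.0

$ greenprofit calibrate
price_low_at_cap:  1.8000
price_high_at_cap: 2.0000
max residual:      0.000000
```

The net-profit column reproduces the published 2-decimal ranking from
each team's gains, costs, duration and average density alone, and one
(low, high) cap-price pair explains all six teams' gains exactly.

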