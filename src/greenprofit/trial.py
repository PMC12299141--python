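"""Published end-of-trial summaries of the 4th Autonomous Greenhouse
Challenge dwarf-tomato cultivation (autumn 2024, Bleiswijk, NL).

Six compartments were each controlled by one team's algorithm.  The table
below records, per team, the harvest measurements and economic totals that
determine the net-profit ranking: red fruit fresh weight (g/pot), red-fruit
dry matter (%), ripe fraction (%), gains and costs (EUR/pot), cultivation
duration (days since transplanting) and the average plant density
(pots/m²).  Costs are stored positive.  These figures are inputs for the
summary evaluation path, the price-cap calibration and the annualized-yield
computation.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # team, red_ffw, dmp, rfp, gains, cost_per_pot, duration, avg_density, net_profit
    ("IDEAS",      219, 6.8, 0.86, 1.05, 0.44, 70, 39.7, 0.34),
    ("MuGrow",     252, 7.3, 0.76, 1.11, 0.74, 70, 33.1, 0.18),
    ("Trigger",    268, 5.9, 1.01, 1.05, 0.73, 80, 33.4, 0.13),
    ("Reference",  275, 6.6, 0.81, 1.05, 0.67, 74, 25.3, 0.13),
    ("Agrifusion", 258, 7.2, 0.92, 1.09, 0.72, 78, 25.0, 0.12),
    ("Tomatonuts", 283, 6.0, 0.98, 1.05, 0.91, 80, 23.0, 0.04),
]

_COLUMNS = ["team", "red_ffw", "dmp", "rfp", "gains", "cost_per_pot",
            "duration_days", "avg_density", "net_profit"]


def trial_summary() -> pd.DataFrame:
    """The six-team end-of-trial summary table, one row per compartment.

    ``net_profit`` is the published (rounded) value, kept for comparison;
    all other columns are inputs.
    """
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
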