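"""Retrospective optimal-harvest-date search.

Given the sparse destructive crop measurements, the realized daily costs
and the density schedule, this module asks: on which day would harvesting
have maximized the net profit?  The red fruit weight and the ripe fraction
are linearly interpolated between measurement dates; the dry-matter
percentage and the cultivation strategy (costs, densities) are frozen at
their realized values, and costs after a hypothetical earlier harvest are
simply not incurred.  The candidate window runs over integer days between
the first and last crop observation, capped at the actual harvest day, and
ties go to the earliest day (a shorter cycle allows more cycles per year).

The fixed-cost spacing charge is recomputed per candidate day: only the
spacing changes realized on or before the candidate day are billed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import crop_value
from .cost_accounting import EquipmentChoice, fixed_costs
from .data_model import (
    CostBook,
    CropObservationSeries,
    DensitySchedule,
    PriceModel,
    ValidationError,
)
from .profit_eval import pot_area_series

logger = logging.getLogger(__name__)

__all__ = ["interpolate_observations", "optimal_harvest_day",
           "HarvestOptimum", "harvest_sensitivity_report"]


def interpolate_observations(obs: CropObservationSeries) -> pd.DataFrame:
    """Daily red fruit weight and ripe fraction by linear interpolation.

    Returns a frame with columns ``day, red_ffw, rfp`` for every integer
    day between the first and last observation.  No extrapolation: the
    frame covers exactly the observed window.
    """
    if len(obs) < 2:
        raise ValidationError("need at least 2 observations to interpolate")
    days = np.array([r.day for r in obs.records], dtype=float)
    red = np.array([r.red_ffw for r in obs.records], dtype=float)
    rfp = np.array([r.red_fruit_fraction for r in obs.records], dtype=float)
    grid = np.arange(int(days[0]), int(days[-1]) + 1)
    return pd.DataFrame({
        "day": grid,
        "red_ffw": np.interp(grid, days, red),
        "rfp": np.interp(grid, days, rfp),
    })


@dataclass
class HarvestOptimum:
    optimal_day: int
    profit_optimal: float        # EUR/m²/day at the optimal day
    actual_day: int
    profit_actual: float         # EUR/m²/day at the realized harvest day
    candidate_days: np.ndarray
    candidate_profits: np.ndarray
    never_sellable: bool = False

    @property
    def days_earlier(self) -> int:
        return self.actual_day - self.optimal_day

    @property
    def profit_delta(self) -> float:
        return self.profit_optimal - self.profit_actual


def optimal_harvest_day(obs: CropObservationSeries,
                        variable_costs: np.ndarray,
                        schedule: DensitySchedule,
                        book: CostBook,
                        model: PriceModel,
                        installed_intensity: float,
                        actual_day: int | None = None) -> HarvestOptimum:
    """Exhaustive scan for the profit-maximizing harvest day.

    Parameters
    ----------
    variable_costs : daily V_d = Ld+Hd+Cd, EUR/m²/day, for days 1..D with
        D at least the last candidate day.
    actual_day : realized harvest day (defaults to the last observation
        day); candidates never extend past it.

    Returns the argmax day (earliest on ties).  If the crop never clears
    the sellability gates within the window, the scan still returns the
    least-negative day and sets ``never_sellable``.
    """
    daily = interpolate_observations(obs)
    if actual_day is None:
        actual_day = int(obs.final.day)
    dmp = obs.final.dry_matter_fraction
    variable_costs = np.asarray(variable_costs, dtype=float)
    upper = min(int(daily["day"].iloc[-1]), actual_day,
                schedule.duration_days, len(variable_costs))
    cand = daily[(daily["day"] >= daily["day"].iloc[0])
                 & (daily["day"] <= upper)]
    if len(cand) == 0:
        raise ValidationError("empty candidate window")
    area = pot_area_series(schedule)

    days = cand["day"].to_numpy(int)
    profits = np.empty(len(days))
    any_sellable = False
    for i, (d, red, rfp) in enumerate(zip(days, cand["red_ffw"],
                                          cand["rfp"])):
        P = crop_value.price(float(red), dmp, float(rfp), model)
        any_sellable = any_sellable or P > 0
        G = crop_value.gains_per_pot(P, book)
        eq = EquipmentChoice(installed_intensity, schedule.n_changes_before(d))
        F = fixed_costs(eq, book)
        a = area[:d]
        cost_per_pot = float(np.sum((F + variable_costs[:d]) * a))
        profits[i] = (G - cost_per_pot) / float(a.sum())

    best = int(np.argmax(profits))  # argmax returns the first (earliest) max
    if not any_sellable:
        logger.warning("crop never clears the sellability gates in the "
                       "candidate window; all candidate profits are negative")
    # profit at the realized harvest day, for the sensitivity report
    if actual_day in days:
        profit_actual = float(profits[days == actual_day][0])
    else:
        profit_actual = float(profits[-1])
    return HarvestOptimum(
        optimal_day=int(days[best]),
        profit_optimal=float(profits[best]),
        actual_day=actual_day,
        profit_actual=profit_actual,
        candidate_days=days,
        candidate_profits=profits,
        never_sellable=not any_sellable,
    )


def harvest_sensitivity_report(result: HarvestOptimum) -> dict:
    """Summarize an optimum as 'days earlier' plus the profit delta.

    The relative gain is reported as ``None`` when the baseline profit is
    not positive (a percentage of a loss is not meaningful).
    """
    delta = result.profit_delta
    if result.profit_actual > 0:
        pct = 100.0 * delta / result.profit_actual
        pct_text = f"{pct:+.0f}%"
    else:
        pct, pct_text = None, "n/a"
    return {
        "optimal_day": result.optimal_day,
        "actual_day": result.actual_day,
        "days_earlier": result.days_earlier,
        "profit_actual": result.profit_actual,
        "profit_optimal": result.profit_optimal,
        "delta_abs": delta,
        "delta_pct": pct,
        "annotation": (f"{result.days_earlier} d earlier: "
                       f"{result.profit_actual:.2f} → "
                       f"{result.profit_optimal:.2f}, "
                       f"{delta:+.2f} ({pct_text})"),
    }
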