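"""The net-profit objective and derived cultivation metrics.

The cultivation objective is the average daily net profit per m² of
greenhouse,

    net profit = (G − Σ_d (F + V_d) · a_d) / Σ_d a_d   [EUR/m²/day],

where G is the gains per pot at harvest, F the daily fixed costs, V_d the
daily variable costs (lamp electricity + heating + CO2, EUR/m²/day) and
a_d = 1/δ_d the greenhouse area one pot occupies on day d under density
δ_d.  The net profit per pot is computed first, then divided by the total
pot-area-days, which equals dividing the daily-average profit per pot by
the average daily area per pot.

Two evaluation paths are exposed: the full-trace path builds the daily
ledger from raw 5-minute records (:func:`evaluate_cultivation`), and the
summary path starts from end-of-trial totals as published in results
tables (:func:`evaluate_summary`).  They agree by construction when the
summary figures come from the full ledger.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cost_accounting, crop_value
from .data_model import (
    ControlTrace,
    CostBook,
    CropObservation,
    CultivationEvaluation,
    DensitySchedule,
    PriceModel,
    ValidationError,
)

__all__ = [
    "pot_area_series", "average_density", "net_profit",
    "annualized_yield", "light_use_efficiency",
    "evaluate_cultivation", "evaluate_summary", "rank_teams",
    "daily_climate_summary",
]


def pot_area_series(schedule: DensitySchedule,
                    duration: int | None = None) -> np.ndarray:
    """Area per pot a_d = 1/δ_d for each day 1..D, m²/pot."""
    return 1.0 / schedule.daily_densities(duration)


def average_density(schedule: DensitySchedule,
                    duration: int | None = None) -> float:
    """Average plant density D / Σ a_d, pots/m².

    This is the harmonic-type mean implied by the objective's denominator:
    the reciprocal of the mean daily area per pot.
    """
    a = pot_area_series(schedule, duration)
    return len(a) / float(a.sum())


def net_profit(G: float, ledger: pd.DataFrame,
               schedule: DensitySchedule) -> float:
    """Average daily net profit, EUR/m²/day.

    ``ledger`` must have columns ``Ld, Hd, Cd, F`` and one row per
    cultivation day, matching the schedule duration.
    """
    if len(ledger) != schedule.duration_days:
        raise ValidationError(
            f"ledger covers {len(ledger)} days, schedule "
            f"{schedule.duration_days}")
    a = pot_area_series(schedule)
    daily = (ledger["F"] + ledger["Ld"] + ledger["Hd"]
             + ledger["Cd"]).to_numpy(float)
    cost_per_pot = float(np.sum(daily * a))
    return (G - cost_per_pot) / float(a.sum())


def annualized_yield(red_ffw: float, avg_density: float, D: int) -> float:
    """Yearly harvest if cycles of this cultivation ran back to back.

    ``red_ffw`` g/pot × density pots/m² gives the per-cycle harvest per m²;
    scaling D days to a year and grams to kg yields kg/m²/year.
    """
    if red_ffw < 0 or avg_density <= 0 or D <= 0:
        raise ValidationError("yield inputs must be positive")
    return red_ffw * avg_density / D * 365.0 / 1000.0


def light_use_efficiency(fresh_weight_per_m2: float,
                         total_par: float) -> float:
    """Grams of fruit fresh weight produced per mol of PAR, per m².

    ``total_par`` is the cultivation-total PAR sum in mol/m², from both
    natural light and lamps.
    """
    if total_par <= 0:
        raise ValidationError("total PAR must be > 0")
    return fresh_weight_per_m2 / total_par


def evaluate_cultivation(trace: ControlTrace,
                         schedule: DensitySchedule,
                         final_obs: CropObservation,
                         book: CostBook,
                         model: PriceModel,
                         team: str | None = None,
                         interventions: int = 0,
                         total_par: float | None = None,
                         installed_intensity: float | None = None,
                         ) -> CultivationEvaluation:
    """Full-trace evaluation: raw 5-minute records to net profit.

    The installed lamp intensity defaults to the trace's peak activation;
    the spacing-change count comes from the schedule.  ``total_par``
    (mol/m² over the cultivation), when given, populates the light-use
    efficiency from the red fruit weight.
    """
    if trace.duration_days != schedule.duration_days:
        raise ValidationError(
            f"trace covers {trace.duration_days} days, schedule "
            f"{schedule.duration_days}")
    ledger = cost_accounting.compute_ledger(
        trace, book, schedule.n_changes, installed_intensity)
    a = pot_area_series(schedule)
    ledger = ledger.assign(ad=a)
    P = crop_value.price(final_obs.red_ffw, final_obs.dry_matter_fraction,
                         final_obs.red_fruit_fraction, model)
    G = crop_value.gains_per_pot(P, book, interventions)
    daily = (ledger["F"] + ledger["Ld"] + ledger["Hd"]
             + ledger["Cd"]).to_numpy(float)
    cost_per_pot = float(np.sum(daily * a))
    profit = (G - cost_per_pot) / float(a.sum())
    density = average_density(schedule)
    D = schedule.duration_days
    return CultivationEvaluation(
        team=team,
        duration_days=D,
        gains_per_pot=G,
        cost_per_pot=cost_per_pot,
        net_profit=profit,
        avg_density=density,
        annualized_yield=annualized_yield(final_obs.red_ffw, density, D),
        lue=(light_use_efficiency(final_obs.red_ffw * density, total_par)
             if total_par else None),
        price_per_pot=P,
        ledger=ledger,
    )


def evaluate_summary(gains: float, cost_per_pot: float, duration_days: int,
                     avg_density: float, team: str | None = None,
                     red_ffw: float | None = None) -> CultivationEvaluation:
    """Summary-path evaluation from end-of-trial totals.

    With a uniform-in-area reading of the totals,
    Σ a_d = D / avg_density, so

        net profit = (G − cost_per_pot) · avg_density / D.
    """
    if duration_days <= 0 or avg_density <= 0:
        raise ValidationError("duration and density must be positive")
    profit = (gains - cost_per_pot) * avg_density / duration_days
    return CultivationEvaluation(
        team=team,
        duration_days=duration_days,
        gains_per_pot=gains,
        cost_per_pot=cost_per_pot,
        net_profit=profit,
        avg_density=avg_density,
        annualized_yield=(annualized_yield(red_ffw, avg_density,
                                           duration_days)
                          if red_ffw is not None else None),
    )


def rank_teams(evaluations: list[CultivationEvaluation]) -> pd.DataFrame:
    """Rank evaluations by net profit, best first.

    Ties are broken by the lower cost per pot (the cheaper cultivation
    wins the tie).
    """
    if not evaluations:
        raise ValidationError("nothing to rank")
    rows = [{
        "team": e.team,
        "net_profit": e.net_profit,
        "gains_per_pot": e.gains_per_pot,
        "cost_per_pot": e.cost_per_pot,
        "duration_days": e.duration_days,
        "avg_density": e.avg_density,
        "annualized_yield": e.annualized_yield,
    } for e in evaluations]
    df = pd.DataFrame(rows)
    df = df.sort_values(["net_profit", "cost_per_pot"],
                        ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def daily_climate_summary(trace: ControlTrace) -> pd.DataFrame:
    """Convenience daily means of the trace's climate channels."""
    df = trace.data[["air_temperature", "lamp_activation"]].copy()
    df["day"] = trace.day_index()
    return df.groupby("day", as_index=False).mean()
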