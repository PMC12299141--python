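"""Daily fixed and variable cost accounting from actuator traces.

Variable costs per day have three components, each derived from the 5-minute
control/state records of a compartment:

* **Lamp electricity** — dimming is linear, so a record at activation *p* %
  draws ``p/100 · I_max / efficacy`` W/m² of electrical power; with 12
  records per hour each record contributes that power for 1/12 h.  Records
  are priced individually by a two-level tariff (on-peak on workday
  daytimes, off-peak otherwise, by the record's local start time).
* **Heating** — a pipe-rail delivers roughly ``2 · max(0, T_pipe − T_air)``
  W/m²; no heat is delivered while the circulation pump is off.
* **CO2 dosing** — the platform records a cumulative dosing-duration counter
  in minutes; each positive per-record increment is converted to mass at a
  fixed dosing rate and priced per kg.  Counter decreases (resets) price 0.

Fixed costs per day combine greenhouse upkeep, lamp depreciation scaled by
the installed lamp intensity, and a charge per spacing change, all annual
rates divided by 365.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    ControlTrace,
    CostBook,
    RECORDS_PER_HOUR,
    ValidationError,
)

__all__ = [
    "EquipmentChoice",
    "lamp_energy_per_record",
    "tariff_prices",
    "electricity_cost",
    "heating_power",
    "heating_cost",
    "co2_cost",
    "fixed_costs",
    "installed_intensity_from_trace",
    "compute_ledger",
]


@dataclass
class EquipmentChoice:
    """Pre-trial equipment decisions that drive the fixed costs."""

    installed_lamp_intensity: float  # µmol/(m² s)
    n_spacing_changes: int           # 0..3

    def __post_init__(self) -> None:
        if self.installed_lamp_intensity < 0:
            raise ValidationError("installed lamp intensity must be >= 0")
        if not 0 <= self.n_spacing_changes <= 3:
            raise ValidationError("spacing changes must be in 0..3")


def lamp_energy_per_record(activation, book: CostBook):
    """Electrical energy of one 5-minute record, kWh/m².

    ``activation`` is the lamp activation percentage in [0, 100]; scalar or
    array.  Linear dimming: 100 % at the default book is
    200/3.2 = 62.5 W/m², i.e. 62.5/1000/12 ≈ 0.0052 kWh per record.
    """
    act = np.asarray(activation, dtype=float)
    if np.any(act < 0) or np.any(act > 100):
        raise ValidationError("activation must lie in [0, 100]")
    watts = act / 100.0 * book.lamp_max_intensity / book.lamp_efficacy
    out = watts / 1000.0 / RECORDS_PER_HOUR
    return out if out.ndim else float(out)


def tariff_prices(index: pd.DatetimeIndex, book: CostBook) -> np.ndarray:
    """EUR/kWh applicable to each record, by its local start time.

    On-peak applies Monday–Friday in [start_hour, end_hour) of the local
    clock (daylight-saving aware); everything else, including all weekend
    hours, is off-peak.
    """
    local = index.tz_convert(book.timezone)
    on_peak = ((local.weekday < 5)
               & (local.hour >= book.on_peak_start_hour)
               & (local.hour < book.on_peak_end_hour))
    return np.where(on_peak, book.on_peak_price, book.off_peak_price)


def electricity_cost(trace: ControlTrace, book: CostBook) -> pd.DataFrame:
    """Daily lamp energy ``EL`` (kWh/m²) and cost ``Ld`` (EUR/m²)."""
    energy = lamp_energy_per_record(
        trace.data["lamp_activation"].to_numpy(float), book)
    prices = tariff_prices(trace.data.index, book)
    day = trace.day_index()
    df = pd.DataFrame({"day": day, "EL": energy, "Ld": energy * prices})
    return df.groupby("day", as_index=False).sum()


def heating_power(pipe_t, air_t, pump_running) -> np.ndarray | float:
    """Instantaneous pipe-rail heat delivery, W/m².

    Zero when the pump is off (a reported pipe temperature without flow
    delivers no heat) or when the pipe is not warmer than the air.
    """
    pipe = np.asarray(pipe_t, dtype=float)
    air = np.asarray(air_t, dtype=float)
    pump = np.asarray(pump_running, dtype=bool)
    p = 2.0 * np.maximum(0.0, np.where(pump, pipe, np.nan) - air)
    p = np.where(pump & np.isfinite(p), p, 0.0)
    return p if p.ndim else float(p)


def heating_cost(trace: ControlTrace, book: CostBook) -> pd.DataFrame:
    """Daily heating energy ``EH`` (kWh/m²) and cost ``Hd`` (EUR/m²)."""
    p = heating_power(trace.data["pipe_temperature"],
                      trace.data["air_temperature"],
                      trace.data["pump_running"])
    energy = np.asarray(p) / 1000.0 / RECORDS_PER_HOUR
    df = pd.DataFrame({"day": trace.day_index(), "EH": energy})
    daily = df.groupby("day", as_index=False).sum()
    daily["Hd"] = daily["EH"] * book.heat_price
    return daily


def co2_cost(trace: ControlTrace, book: CostBook) -> pd.DataFrame:
    """Daily CO2 mass (kg/m²) and cost ``Cd`` (EUR/m²).

    Only positive increments of the cumulative dosing-duration counter are
    priced, so counter resets contribute nothing.
    """
    counter = trace.data["co2_dosing_cumulative"].to_numpy(float)
    minutes = np.maximum(0.0, np.diff(counter, prepend=counter[0]))
    grams = minutes * book.co2_rate
    df = pd.DataFrame({"day": trace.day_index(), "co2_kg": grams / 1000.0})
    daily = df.groupby("day", as_index=False).sum()
    daily["Cd"] = daily["co2_kg"] * book.co2_price
    return daily


def fixed_costs(equipment: EquipmentChoice, book: CostBook) -> float:
    """Daily fixed costs ``F``, EUR/m²/day."""
    return (book.base_fixed / 365.0
            + book.lamp_depreciation / 365.0 * equipment.installed_lamp_intensity
            + book.spacing_step_cost / 365.0 * equipment.n_spacing_changes)


def installed_intensity_from_trace(trace: ControlTrace,
                                   book: CostBook) -> float:
    """Installed lamp intensity, µmol/(m² s), from the peak activation used.

    The equipment charge is driven by the maximum activation percentage
    reached at any point of the trace (the whole trial, including any
    pre-freeze tuning window it covers).
    """
    peak = float(trace.data["lamp_activation"].max())
    return peak / 100.0 * book.lamp_max_intensity


def compute_ledger(trace: ControlTrace, book: CostBook,
                   n_spacing_changes: int,
                   installed_intensity: float | None = None) -> pd.DataFrame:
    """Full daily cost ledger for a trace.

    Columns: ``day, EL, Ld, EH, Hd, co2_kg, Cd, F``.  When
    ``installed_intensity`` is None it is inferred from the trace's peak
    lamp activation.
    """
    if installed_intensity is None:
        installed_intensity = installed_intensity_from_trace(trace, book)
    equipment = EquipmentChoice(installed_intensity, n_spacing_changes)
    elec = electricity_cost(trace, book)
    heat = heating_cost(trace, book)
    co2 = co2_cost(trace, book)
    ledger = elec.merge(heat, on="day").merge(co2, on="day")
    ledger["F"] = fixed_costs(equipment, book)
    return ledger
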