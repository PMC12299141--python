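import numpy as np
import pandas as pd
import pytest

from greenprofit.data_model import ControlTrace, CostBook, CropObservation, PriceModel

RECORDS_PER_DAY = 288


@pytest.fixture
def book() -> CostBook:
    return CostBook()


@pytest.fixture
def model() -> PriceModel:
    return PriceModel()


def build_trace(n_days: int = 2,
                start: str = "2024-09-02",   # a Monday
                tz: str = "UTC",
                lamp=None, air=None, pipe=None, pump=None, co2=None
                ) -> ControlTrace:
    """Assemble a trace from per-record arrays (defaults: everything idle)."""
    n = RECORDS_PER_DAY * n_days
    idx = pd.date_range(start, periods=n, freq="5min", tz=tz)
    frame = pd.DataFrame({
        "lamp_activation": np.zeros(n) if lamp is None else lamp,
        "air_temperature": np.full(n, 20.0) if air is None else air,
        "pipe_temperature": np.full(n, np.nan) if pipe is None else pipe,
        "pump_running": np.zeros(n, bool) if pump is None else pump,
        "co2_dosing_cumulative": np.zeros(n) if co2 is None else co2,
    }, index=idx)
    return ControlTrace(frame)


@pytest.fixture
def toy_trace() -> ControlTrace:
    """3-day trace with a fully hand-computable ledger.

    Per day: lamps at 100 % for 8 h (08:00–16:00 UTC, entirely on-peak in
    local CEST time on Mon–Wed), pipe 45 °C over 20 °C air with the pump on
    for 2 h each night, and 60 min of CO2 dosing between 10:00 and 11:00.
    """
    n = RECORDS_PER_DAY * 3
    idx = pd.date_range("2024-09-02", periods=n, freq="5min", tz="UTC")
    hour = idx.hour
    lamp = np.where((hour >= 8) & (hour < 16), 100.0, 0.0)
    pump = hour < 2
    pipe = np.where(pump, 45.0, np.nan)
    co2 = np.cumsum(np.where(hour == 10, 5.0, 0.0))
    return build_trace(3, lamp=lamp, pipe=pipe, pump=pump, co2=co2)


# hand-computed (spreadsheet-style) daily ledger of ``toy_trace`` under the
# default cost book, installed intensity 200 µmol/(m² s), 0 spacing changes
TOY_DAILY = {
    "EL": 0.5,                      # 96 records × 0.00520833… kWh
    "Ld": 0.15,                     # all on-peak at 0.30 EUR/kWh
    "EH": 0.1,                      # 24 records × 50 W/m² / 1000 / 12
    "Hd": 0.009,
    "co2_kg": 0.0075,               # 60 min × 0.125 g
    "Cd": 0.00225,
    "F": 0.08801369863013699,       # (18.125 + 0.07·200)/365
}
TOY_FINAL_OBS = CropObservation(day=3, total_ffw=240.0, red_ffw=200.0,
                                red_fruit_fraction=200.0 / 240.0,
                                dry_matter_fraction=7.5)
TOY_COST_PER_POT = 0.013353412426614482   # 3 days × (F+Vd) / 56
TOY_GAINS = 1.15                          # price 1.90 (dmp midpoint) − 0.75
TOY_NET_PROFIT = 21.21740296803653        # (G − cost/pot)·56/3
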