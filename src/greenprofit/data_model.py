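"""Domain types and readers/writers for cultivation evaluation.

The central objects are:

* :class:`ControlTrace` — uniformly sampled 5-minute actuator/state records
  for one greenhouse compartment over a full cultivation cycle.
* :class:`DensitySchedule` — the piecewise-constant plant density
  (pots per m²) over days since transplanting, with spacing-change events.
* :class:`CropObservationSeries` — sparse destructive crop measurements
  (fruit fresh weights, ripeness, dry matter).
* :class:`CostBook` / :class:`PriceModel` — all economic constants.
* :class:`CultivationEvaluation` — the per-day cost ledger plus
  end-of-cultivation gains, net profit and derived agronomic metrics.

All traces are timezone-aware.  A cultivation *day* is a local-clock
midnight-to-midnight window (day 1 = transplant day), so a trace is valid
when every covered local date is complete at the 300 s sampling step —
including the 23 h / 25 h days around daylight-saving transitions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

STEP_SECONDS = 300
RECORDS_PER_HOUR = 12

#: density levels the spacing system supports, pots/m², in spacing order
ALLOWED_DENSITIES = (56, 42, 30, 20)

#: canonical trace channel names
TRACE_CHANNELS = (
    "lamp_activation",
    "air_temperature",
    "pipe_temperature",
    "pump_running",
    "co2_dosing_cumulative",
)


class ValidationError(ValueError):
    """An input violates a domain invariant."""


# ---------------------------------------------------------------------------
# economic configuration
# ---------------------------------------------------------------------------

@dataclass
class CostBook:
    """Economic constants of the cultivation trial.

    Monetary units are EUR throughout.  Annual rates (``base_fixed``,
    ``lamp_depreciation``, ``spacing_step_cost``) are converted to daily
    rates by dividing by 365.
    """

    base_fixed: float = 18.1250            # EUR/m²/year, greenhouse upkeep
    lamp_depreciation: float = 0.07        # EUR per µmol/(m² s) per year
    spacing_step_cost: float = 1.50        # EUR/m²/year per spacing change
    on_peak_price: float = 0.30            # EUR/kWh, workday daytime
    off_peak_price: float = 0.20           # EUR/kWh, nights and weekends
    on_peak_start_hour: int = 7            # inclusive, local clock
    on_peak_end_hour: int = 23             # exclusive, local clock
    heat_price: float = 0.09               # EUR/kWh
    co2_rate: float = 0.125                # g CO2 per m² per dosing minute
    co2_price: float = 0.30                # EUR/kg
    plant_cost: float = 0.75               # EUR per pot (seed+pot+propagation)
    lamp_max_intensity: float = 200.0      # µmol/(m² s) at 100% activation
    lamp_efficacy: float = 3.2             # µmol/J
    intervention_penalty: float = 0.10     # EUR/pot per manual intervention
    penalty_enabled: bool = False
    timezone: str = "Europe/Amsterdam"

    def __post_init__(self) -> None:
        for name in ("base_fixed", "lamp_depreciation", "spacing_step_cost",
                     "on_peak_price", "off_peak_price", "heat_price",
                     "co2_rate", "co2_price", "plant_cost",
                     "lamp_max_intensity", "lamp_efficacy",
                     "intervention_penalty"):
            if getattr(self, name) < 0:
                raise ValidationError(f"CostBook.{name} must be >= 0")
        if not 0 <= self.on_peak_start_hour < self.on_peak_end_hour <= 24:
            raise ValidationError("on-peak window must satisfy 0 <= start < end <= 24")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostBook":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PriceModel:
    """Piecewise price of one pot as a function of fruit quality.

    A pot is unsellable (price 0) when the ripe-fruit fraction is below
    ``ripeness_min`` or the ripe fresh fruit weight is below ``ffw_min``.
    Otherwise the price at the weight cap interpolates linearly on the
    dry-matter axis between ``price_low_at_cap`` (dmp <= ``dm_low`` %) and
    ``price_high_at_cap`` (dmp >= ``dm_high`` %).  Below the cap the price
    follows ``sub_cap_shape``; above the cap it is flat.
    """

    ripeness_min: float = 1.0 / 3.0   # fraction of fruit weight that is red
    ffw_min: float = 50.0             # g/pot, minimum sellable red weight
    ffw_cap: float = 150.0            # g/pot, weight above which price is flat
    dm_low: float = 7.0               # %, at or below -> low price curve
    dm_high: float = 8.0              # %, at or above -> high price curve
    price_low_at_cap: float = 1.80    # EUR at the cap, low dry matter
    price_high_at_cap: float = 2.00   # EUR at the cap, high dry matter
    sub_cap_shape: str = "proportional"  # "proportional" | "flat"

    def __post_init__(self) -> None:
        if not 0 < self.ffw_min < self.ffw_cap:
            raise ValidationError("need 0 < ffw_min < ffw_cap")
        if not self.dm_low < self.dm_high:
            raise ValidationError("need dm_low < dm_high")
        if self.price_low_at_cap < 0 or self.price_high_at_cap < 0:
            raise ValidationError("cap prices must be >= 0")
        if self.sub_cap_shape not in ("proportional", "flat"):
            raise ValidationError(f"unknown sub_cap_shape {self.sub_cap_shape!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriceModel":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# control trace
# ---------------------------------------------------------------------------

@dataclass
class ControlTrace:
    """5-minute actuator/state records for one compartment.

    ``data`` is indexed by a tz-aware DatetimeIndex at a strict 300 s step
    and carries the columns in :data:`TRACE_CHANNELS`.  ``pipe_temperature``
    may be NaN while the circulation pump is off (no heat delivery).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex) or idx.tz is None:
            raise ValidationError("trace index must be a tz-aware DatetimeIndex")
        if len(idx) == 0:
            raise ValidationError("empty trace")
        missing = [c for c in TRACE_CHANNELS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing channels: {missing}")
        step = np.diff(idx.asi8) / 1e9
        if len(step) and not np.all(step == STEP_SECONDS):
            bad = int(np.argmax(step != STEP_SECONDS))
            raise ValidationError(
                f"timestamps must increase at a constant {STEP_SECONDS} s step "
                f"(violated after {idx[bad]})")
        act = self.data["lamp_activation"].to_numpy(float)
        if np.any(act < 0) or np.any(act > 100) or np.any(~np.isfinite(act)):
            raise ValidationError("lamp_activation must lie in [0, 100]")
        self._validate_complete_days()
        co2 = self.data["co2_dosing_cumulative"].to_numpy(float)
        drops = int(np.sum(np.diff(co2) < 0))
        if drops:
            # counter resets happen when the data platform restarts; the
            # positive-difference costing rule makes them harmless
            logger.warning("CO2 cumulative counter decreases %d time(s); "
                           "treated as counter resets", drops)

    def _validate_complete_days(self) -> None:
        idx = self.data.index
        midnights = idx.normalize()
        counts = pd.Series(1, index=midnights).groupby(level=0).sum()
        for midnight, n in counts.items():
            nxt = (midnight.tz_localize(None) + pd.Timedelta(days=1)
                   ).tz_localize(midnight.tz)
            expected = int((nxt - midnight).total_seconds() // STEP_SECONDS)
            if n != expected:
                raise ValidationError(
                    f"day starting {midnight.date()} has {n} records, "
                    f"expected {expected}")
        first = idx[0]
        if first != first.normalize():
            raise ValidationError("trace must start at local midnight")

    # -- derived views ------------------------------------------------------

    @property
    def duration_days(self) -> int:
        return len(self.data.index.normalize().unique())

    def day_index(self) -> np.ndarray:
        """1-based cultivation day of every record (day 1 = first local date)."""
        dates = self.data.index.normalize()
        codes, _ = pd.factorize(dates, sort=True)
        return codes + 1


def read_control_trace(path: str | Path,
                       dialect: dict[str, str] | None = None,
                       tz: str = "Europe/Amsterdam",
                       max_gap_records: int = 6) -> ControlTrace:
    """Read a control trace from CSV and validate it.

    ``dialect`` maps canonical channel names (and ``"timestamp"``) to the
    CSV's column names.  Gaps of at most ``max_gap_records`` consecutive
    missing 5-minute records are filled — last observation carried forward
    for state channels, linear interpolation for the cumulative CO2 dosing
    counter — with a logged warning; longer gaps raise
    :class:`ValidationError`.  Naive timestamps are localized to ``tz``.
    """
    dialect = dialect or {}
    colmap = {dialect.get(name, name): name
              for name in ("timestamp", *TRACE_CHANNELS)}
    raw = pd.read_csv(path)
    raw = raw.rename(columns=colmap)
    if "timestamp" not in raw.columns:
        raise ValidationError("no timestamp column found")
    required = [c for c in TRACE_CHANNELS
                if c not in ("pipe_temperature", "pump_running")]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"missing required channels: {missing}")

    with warnings.catch_warnings():
        # mixed UTC offsets (a trace spanning a DST transition) parse to
        # object dtype; re-parse via UTC in that case
        warnings.simplefilter("ignore", FutureWarning)
        ts = pd.to_datetime(raw["timestamp"], utc=False, format="ISO8601")
    if ts.dtype == object:
        ts = pd.to_datetime(raw["timestamp"], utc=True, format="ISO8601")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz)
    else:
        ts = ts.dt.tz_convert(tz)
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValidationError("timestamps must be strictly increasing")

    frame = raw.drop(columns=["timestamp"]).set_index(pd.DatetimeIndex(ts))
    if "pipe_temperature" not in frame.columns:
        frame["pipe_temperature"] = np.nan
    if "pump_running" not in frame.columns:
        # no pump state channel: assume the pump runs whenever a pipe
        # temperature is reported
        logger.warning("pump_running channel absent; inferring from "
                       "pipe_temperature availability")
        frame["pump_running"] = frame["pipe_temperature"].notna()

    full = pd.date_range(frame.index[0], frame.index[-1],
                         freq=f"{STEP_SECONDS}s", tz=tz)
    frame = frame.reindex(full)
    frame["pump_running"] = frame["pump_running"].astype("boolean")
    gap = frame["lamp_activation"].isna()
    n_missing = int(gap.sum())
    if n_missing:
        runs = gap.astype(int).groupby((~gap).cumsum()).sum()
        longest = int(runs.max())
        if longest > max_gap_records:
            raise ValidationError(
                f"gap of {longest} consecutive records exceeds the "
                f"{max_gap_records}-record fill limit")
        logger.warning("filled %d missing record(s) (longest run %d)",
                       n_missing, longest)
        co2 = frame["co2_dosing_cumulative"].interpolate(method="time")
        frame = frame.ffill()
        frame["co2_dosing_cumulative"] = co2

    frame["pump_running"] = frame["pump_running"].astype(bool)
    frame = frame[list(TRACE_CHANNELS)]
    return ControlTrace(frame)


def write_control_trace(trace: ControlTrace, path: str | Path) -> None:
    """Write a trace to CSV with ISO-8601 timestamps (lossless round trip)."""
    out = trace.data.copy()
    out.insert(0, "timestamp", out.index.map(lambda t: t.isoformat()))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# density schedule
# ---------------------------------------------------------------------------

@dataclass
class DensitySchedule:
    """Piecewise-constant plant density over days since transplanting.

    ``events`` is a list of ``(day, density)`` pairs; a spacing event on day
    *k* makes the new density effective from day *k* onward.  The trial's
    spacing system starts at 56 pots/m² and allows stepping down through
    42, 30 and 20, skipping steps, with at most three changes.
    """

    events: list[tuple[int, int]]
    duration_days: int

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValidationError("duration_days must be >= 1")
        if not self.events:
            raise ValidationError("schedule needs at least the initial density")
        days = [d for d, _ in self.events]
        dens = [x for _, x in self.events]
        if days[0] != 1:
            raise ValidationError("first density event must be on day 1")
        if dens[0] != ALLOWED_DENSITIES[0]:
            raise ValidationError(
                f"initial density must be {ALLOWED_DENSITIES[0]} pots/m²")
        for x in dens:
            if x not in ALLOWED_DENSITIES:
                raise ValidationError(
                    f"density {x} not in allowed set {ALLOWED_DENSITIES}")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("event days must be strictly increasing")
        if any(b >= a for a, b in zip(dens, dens[1:])):
            raise ValidationError("densities must strictly decrease")
        if len(self.events) - 1 > 3:
            raise ValidationError("at most 3 spacing changes are allowed")
        if days[-1] > self.duration_days:
            raise ValidationError("event day beyond cultivation duration")

    @property
    def n_changes(self) -> int:
        return len(self.events) - 1

    def n_changes_before(self, day: int) -> int:
        """Spacing changes realized on or before ``day``."""
        return sum(1 for d, _ in self.events[1:] if d <= day)

    def daily_densities(self, duration: int | None = None) -> np.ndarray:
        """Density in pots/m² for each day 1..D."""
        D = duration if duration is not None else self.duration_days
        if D > self.duration_days:
            raise ValidationError("requested duration exceeds schedule")
        out = np.empty(D)
        days = np.array([d for d, _ in self.events])
        dens = np.array([x for _, x in self.events], dtype=float)
        pos = np.searchsorted(days, np.arange(1, D + 1), side="right") - 1
        out[:] = dens[pos]
        return out

    @classmethod
    def from_csv(cls, path: str | Path, duration_days: int) -> "DensitySchedule":
        df = pd.read_csv(path)
        events = [(int(r.day), int(r.density)) for r in df.itertuples()]
        return cls(events, duration_days)

    @classmethod
    def from_json(cls, path: str | Path) -> "DensitySchedule":
        with open(path) as fh:
            data = json.load(fh)
        return cls([(int(d), int(x)) for d, x in data["events"]],
                   int(data["duration_days"]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.events, columns=["day", "density"]).to_csv(
            path, index=False)


def read_density_schedule(path: str | Path,
                          duration_days: int | None = None) -> DensitySchedule:
    """Read a density schedule from CSV (needs ``duration_days``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return DensitySchedule.from_json(path)
    if duration_days is None:
        raise ValidationError("duration_days required for CSV schedules")
    return DensitySchedule.from_csv(path, duration_days)


# ---------------------------------------------------------------------------
# crop observations
# ---------------------------------------------------------------------------

@dataclass
class CropObservation:
    day: int
    total_ffw: float            # g/pot, all fruit
    red_ffw: float              # g/pot, ripe fruit only
    red_fruit_fraction: float   # red over total fresh weight (may exceed 1)
    dry_matter_fraction: float  # percent dry over fresh mass of ripe fruit


@dataclass
class CropObservationSeries:
    """Sparse destructive crop measurements over the cultivation.

    Because successive destructive measurements sample *different* plants,
    the red weight can slightly exceed the total weight of an earlier (or
    even the same) measurement date; such records are flagged, not rejected.
    """

    records: list[CropObservation]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("observation days must be strictly increasing")
        for r in self.records:
            if r.total_ffw < 0 or r.red_ffw < 0:
                raise ValidationError("fruit weights must be >= 0")
            if r.red_ffw > r.total_ffw * 1.0 + 1e-12 and \
                    f"day {r.day}: red > total" not in self.flags:
                self.flags.append(f"day {r.day}: red > total")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final(self) -> CropObservation:
        return self.records[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CropObservationSeries":
        recs = []
        for r in df.itertuples():
            rfp = getattr(r, "red_fruit_fraction", None)
            if rfp is None or (isinstance(rfp, float) and np.isnan(rfp)):
                rfp = r.red_ffw / r.total_ffw if r.total_ffw > 0 else 0.0
            recs.append(CropObservation(int(r.day), float(r.total_ffw),
                                        float(r.red_ffw), float(rfp),
                                        float(r.dry_matter_fraction)))
        return cls(recs)


def read_crop_observations(path: str | Path) -> CropObservationSeries:
    return CropObservationSeries.from_frame(pd.read_csv(path))


def write_crop_observations(obs: CropObservationSeries,
                            path: str | Path) -> None:
    obs.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# evaluation result
# ---------------------------------------------------------------------------

@dataclass
class CultivationEvaluation:
    """Complete economic evaluation of one cultivation.

    ``ledger`` has one row per day with columns
    ``day, EL, Ld, EH, Hd, co2_kg, Cd, F, ad`` (energies kWh/m², costs
    EUR/m²/day, ``ad`` m²/pot).  The ledger is ``None`` for evaluations
    built from end-of-trial summary figures only.
    """

    team: str | None
    duration_days: int
    gains_per_pot: float        # G, EUR/pot
    cost_per_pot: float         # Σ (F+Vd)·ad, EUR/pot
    net_profit: float           # EUR/m²/day
    avg_density: float          # pots/m²
    annualized_yield: float | None = None   # kg/m²/year
    lue: float | None = None                # g fresh weight per mol PAR
    price_per_pot: float | None = None      # P, EUR
    ledger: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "ledger"}
        d["ledger"] = (None if self.ledger is None
                       else self.ledger.to_dict(orient="list"))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CultivationEvaluation":
        d = dict(d)
        led = d.pop("ledger", None)
        return cls(ledger=None if led is None else pd.DataFrame(led), **d)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits,
                                           rounding=ROUND_HALF_UP))


def write_evaluation_report(evaluation: CultivationEvaluation,
                            out_dir: str | Path) -> dict[str, Path]:
    """Write the daily ledger (CSV) and a summary (JSON) for an evaluation.

    The machine-readable ``evaluation.json`` keeps full float precision and
    round-trips through :meth:`CultivationEvaluation.from_dict`; the
    human-readable ``summary.json`` rounds money half-up to 2 decimals.
    """
    if evaluation.ledger is not None and len(evaluation.ledger) == 0:
        raise ValidationError("refusing to report an empty ledger")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if evaluation.ledger is not None:
        paths["ledger"] = out_dir / "ledger.csv"
        evaluation.ledger.to_csv(paths["ledger"], index=False)
    paths["machine"] = out_dir / "evaluation.json"
    with open(paths["machine"], "w") as fh:
        json.dump(evaluation.to_dict(), fh)
    summary = {
        "team": evaluation.team,
        "duration_days": evaluation.duration_days,
        "gains_per_pot": f"{_round_half_up(evaluation.gains_per_pot):.2f}",
        "cost_per_pot": f"{_round_half_up(evaluation.cost_per_pot):.2f}",
        "net_profit": f"{_round_half_up(evaluation.net_profit):.2f}",
        "avg_density": round(evaluation.avg_density, 1),
    }
    if evaluation.annualized_yield is not None:
        summary["annualized_yield"] = round(evaluation.annualized_yield)
    paths["summary"] = out_dir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths


def read_evaluation(path: str | Path) -> CultivationEvaluation:
    with open(path) as fh:
        return CultivationEvaluation.from_dict(json.load(fh))
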