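"""Seeded generators for traces, schedules and crop observations.

The trial's raw data (5-minute actuator records, sparse destructive crop
measurements) is emulated here so the whole pipeline is testable without
any download.  The generator reproduces the *statistical structure* the
cost and profit computations care about — photoperiod-gated lamp dimming,
day/night air temperature, a night-time pipe-rail heating window, a
cumulative CO2 dosing counter, stepwise plant-density reduction, and
saturating (logistic) fruit growth with delayed ripening — not greenhouse
physics.

All randomness derives from one root seed through named
:class:`numpy.random.SeedSequence` streams, so traces and crop series can
be regenerated independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_model import (
    ControlTrace,
    CostBook,
    CropObservation,
    CropObservationSeries,
    DensitySchedule,
    PriceModel,
    STEP_SECONDS,
    ValidationError,
)

__all__ = ["ScenarioConfig", "ScenarioBundle", "generate_trace",
           "generate_crop_series", "generate_schedule",
           "generate_benchmark_suite", "naive_daily_ledger",
           "logistic", "fit_logistic"]


def logistic(t, K, r, t0):
    """K / (1 + exp(−r·(t − t0))): the saturating growth curve used for
    total fruit weight and (scaled) for the ripe fraction."""
    return K / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t0)))


def fit_logistic(days, values, p0=None):
    """Least-squares logistic refit; returns (K, r, t0)."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if p0 is None:
        p0 = (float(values.max()) * 1.05, 0.1, float(np.median(days)))
    popt, _ = curve_fit(logistic, days, values, p0=p0, maxfev=20000)
    return tuple(float(v) for v in popt)


@dataclass
class ScenarioConfig:
    """One compartment's simulated cultivation scenario.

    Defaults match the trial's conditions: transplanting in early September
    with a 70-day cycle, lamps dimmed around 60 % of a 200 µmol/(m² s)
    installation over a 16 h photoperiod, ~20–22 °C air, a night heating
    window, ~2 h of CO2 dosing per day spread over the daytime, the
    56→42→30→20 spacing ladder, and fruit saturating at 250–300 g/pot with
    most fruits ripe by day 70.
    """

    seed: int = 0
    duration_days: int = 70
    start_date: str = "2024-09-03"         # transplant day (local midnight)
    timezone: str = "Europe/Amsterdam"
    # lamps
    photoperiod_hours: float = 16.0
    lamp_on_hour: int = 6
    lamp_mean_activation: float = 60.0     # % of installed intensity
    lamp_noise_sd: float = 5.0             # % dimming noise per record
    lamp_max_activation: float = 100.0     # dimming ceiling, %
    # air and heating
    day_air_temp: float = 21.5             # °C during the photoperiod
    night_air_temp: float = 19.0           # °C otherwise
    air_noise_sd: float = 0.3
    pipe_offset: float = 10.0              # °C pipe above air while heating
    heating_start_hour: int = 0
    heating_end_hour: int = 7
    # CO2
    co2_dosing_min_per_day: float = 120.0  # dosing minutes per day
    co2_start_hour: int = 8
    co2_end_hour: int = 18
    # spacing
    density_events: list[tuple[int, int]] = field(
        default_factory=lambda: [(1, 56), (25, 42), (45, 30), (60, 20)])
    # crop growth (logistic in total fresh fruit weight)
    crop_K: float = 280.0                  # g/pot asymptote
    crop_r: float = 0.12                   # 1/day
    crop_t0: float = 45.0                  # day of the inflection
    # ripening (logistic ripe fraction)
    ripen_r: float = 0.25                  # 1/day
    ripen_t0: float = 56.0                 # day at 50 % ripe
    dmp: float = 6.8                       # red-fruit dry matter, %
    noise_sd: float = 5.0                  # g/pot observation noise
    obs_days: tuple[int, ...] | None = None  # default (34, 49, 63, harvest)

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValidationError("duration_days must be >= 1")
        for name in ("photoperiod_hours", "crop_K", "crop_r", "ripen_r"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.lamp_mean_activation <= self.lamp_max_activation <= 100:
            raise ValidationError(
                "need 0 <= mean activation <= max activation <= 100")

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent, reproducible RNG streams derived from the seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("lamp", "air", "pipe", "crop")
        return {name: np.random.default_rng(child)
                for name, child in zip(names, root.spawn(len(names)))}


def _local_index(cfg: ScenarioConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start_date).tz_localize(cfg.timezone)
    end = (pd.Timestamp(cfg.start_date) + pd.Timedelta(days=cfg.duration_days)
           ).tz_localize(cfg.timezone)
    return pd.date_range(start, end, freq=f"{STEP_SECONDS}s",
                         inclusive="left", tz=cfg.timezone)


def generate_trace(cfg: ScenarioConfig) -> ControlTrace:
    """Simulate the 5-minute actuator/state records of one compartment."""
    idx = _local_index(cfg)
    rng = cfg.streams()
    hour = idx.hour + idx.minute / 60.0

    in_photoperiod = ((hour - cfg.lamp_on_hour) % 24) < cfg.photoperiod_hours
    activation = np.where(
        in_photoperiod,
        np.clip(rng["lamp"].normal(cfg.lamp_mean_activation,
                                   cfg.lamp_noise_sd, len(idx)),
                0.0, cfg.lamp_max_activation),
        0.0)

    air = np.where(in_photoperiod, cfg.day_air_temp, cfg.night_air_temp)
    air = air + rng["air"].normal(0.0, cfg.air_noise_sd, len(idx))

    heating = (hour >= cfg.heating_start_hour) & (hour < cfg.heating_end_hour)
    pipe = np.where(
        heating,
        air + np.clip(cfg.pipe_offset
                      + rng["pipe"].normal(0.0, 1.0, len(idx)), 0.0, None),
        np.nan)

    dosing = (hour >= cfg.co2_start_hour) & (hour < cfg.co2_end_hour)
    window_records = (cfg.co2_end_hour - cfg.co2_start_hour) * 12
    per_record = (cfg.co2_dosing_min_per_day / window_records
                  if window_records else 0.0)
    counter = np.cumsum(np.where(dosing, per_record, 0.0))

    frame = pd.DataFrame({
        "lamp_activation": activation,
        "air_temperature": air,
        "pipe_temperature": pipe,
        "pump_running": heating,
        "co2_dosing_cumulative": counter,
    }, index=idx)
    return ControlTrace(frame)


def generate_schedule(cfg: ScenarioConfig) -> DensitySchedule:
    # spacing events after the harvest day never happen
    events = [(d, x) for d, x in cfg.density_events
              if d <= cfg.duration_days]
    return DensitySchedule(events, cfg.duration_days)


def generate_crop_series(cfg: ScenarioConfig,
                         obs_days: tuple[int, ...] | None = None
                         ) -> CropObservationSeries:
    """Sparse destructive observations from noiseless logistic trajectories
    plus seeded Gaussian weight noise.

    Default measurement dates mirror the trial's cadence (three mid-cycle
    destructive measurements around days 34, 49 and 63, plus the harvest
    day), clipped to the cultivation window.
    """
    if obs_days is None:
        obs_days = cfg.obs_days
    if obs_days is None:
        obs_days = tuple(sorted({min(d, cfg.duration_days)
                                 for d in (34, 49, 63, cfg.duration_days)}))
    rng = cfg.streams()["crop"]
    records = []
    for day in obs_days:
        total_true = float(logistic(day, cfg.crop_K, cfg.crop_r, cfg.crop_t0))
        rfp_true = float(logistic(day, 1.0, cfg.ripen_r, cfg.ripen_t0))
        red_true = rfp_true * total_true
        total = max(0.0, total_true + rng.normal(0.0, cfg.noise_sd))
        red = min(max(0.0, red_true + rng.normal(0.0, cfg.noise_sd)), total)
        rfp = red / total if total > 0 else 0.0
        records.append(CropObservation(int(day), total, red, rfp, cfg.dmp))
    return CropObservationSeries(records)


def naive_daily_ledger(trace: ControlTrace, book: CostBook,
                       n_spacing_changes: int,
                       installed_intensity: float | None = None
                       ) -> pd.DataFrame:
    """Per-record loop re-computation of the daily cost ledger.

    Deliberately written as a plain Python loop over records — an
    independent oracle for the vectorized accounting path, and the ground
    truth retained with generated benchmark bundles.
    """
    data = trace.data
    if installed_intensity is None:
        installed_intensity = (max(data["lamp_activation"]) / 100.0
                               * book.lamp_max_intensity)
    F = (book.base_fixed / 365.0
         + book.lamp_depreciation / 365.0 * installed_intensity
         + book.spacing_step_cost / 365.0 * n_spacing_changes)
    days = trace.day_index()
    act = data["lamp_activation"].to_list()
    air = data["air_temperature"].to_list()
    pipe = data["pipe_temperature"].to_list()
    pump = data["pump_running"].to_list()
    counter = data["co2_dosing_cumulative"].to_list()
    weekdays = list(data.index.weekday)
    hours = list(data.index.hour)
    rows: dict[int, dict[str, float]] = {}
    prev_counter = counter[0]
    for i in range(len(data)):
        d = int(days[i])
        row = rows.setdefault(d, {"EL": 0.0, "Ld": 0.0, "EH": 0.0,
                                  "Hd": 0.0, "co2_kg": 0.0, "Cd": 0.0})
        el = (act[i] / 100.0 * book.lamp_max_intensity
              / book.lamp_efficacy / 1000.0 / 12.0)
        on_peak = (weekdays[i] < 5
                   and book.on_peak_start_hour <= hours[i]
                   < book.on_peak_end_hour)
        row["EL"] += el
        row["Ld"] += el * (book.on_peak_price if on_peak
                           else book.off_peak_price)
        if pump[i] and np.isfinite(pipe[i]):
            p = 2.0 * max(0.0, pipe[i] - air[i])
            row["EH"] += p / 1000.0 / 12.0
            row["Hd"] += p / 1000.0 / 12.0 * book.heat_price
        inc = max(0.0, counter[i] - prev_counter)
        prev_counter = counter[i]
        row["co2_kg"] += inc * book.co2_rate / 1000.0
        row["Cd"] += inc * book.co2_rate / 1000.0 * book.co2_price
    out = pd.DataFrame([{"day": d, **row} for d, row in sorted(rows.items())])
    out["F"] = F
    return out


@dataclass
class ScenarioBundle:
    """One simulated compartment plus its retained ground truth."""

    name: str
    config: ScenarioConfig
    trace: ControlTrace
    schedule: DensitySchedule
    observations: CropObservationSeries
    ledger_truth: pd.DataFrame | None
    book: CostBook
    model: PriceModel


# six scenario templates spanning the trial's spacing strategies (1–3
# changes, early to very late), lighting intensities and crop outcomes;
# average densities land in the observed 23–40 pots/m² span
_TEMPLATES: tuple[dict, ...] = (
    dict(duration_days=70, density_events=[(1, 56), (42, 30), (64, 20)],
         lamp_max_activation=100, lamp_mean_activation=65,
         photoperiod_hours=16, crop_K=280, crop_t0=45, dmp=6.8,
         ripen_t0=55),
    dict(duration_days=70, density_events=[(1, 56), (25, 42), (45, 30),
                                           (60, 20)],
         lamp_max_activation=95, lamp_mean_activation=80,
         photoperiod_hours=18, crop_K=300, crop_t0=47, dmp=7.3,
         ripen_t0=58),
    dict(duration_days=80, density_events=[(1, 56), (22, 42), (40, 30),
                                           (55, 20)],
         lamp_max_activation=90, lamp_mean_activation=55,
         photoperiod_hours=15, crop_K=290, crop_t0=48, dmp=5.9,
         ripen_t0=60),
    dict(duration_days=74, density_events=[(1, 56), (15, 42), (30, 30),
                                           (45, 20)],
         lamp_max_activation=80, lamp_mean_activation=50,
         photoperiod_hours=14, crop_K=295, crop_t0=46, dmp=6.6,
         ripen_t0=57),
    dict(duration_days=78, density_events=[(1, 56), (18, 20)],
         lamp_max_activation=85, lamp_mean_activation=60,
         photoperiod_hours=16, crop_K=270, crop_t0=44, dmp=7.2,
         ripen_t0=59),
    dict(duration_days=80, density_events=[(1, 56), (8, 42), (20, 30),
                                           (35, 20)],
         lamp_max_activation=75, lamp_mean_activation=45,
         photoperiod_hours=13, crop_K=300, crop_t0=50, dmp=6.0,
         ripen_t0=62),
)


def generate_benchmark_suite(n_compartments: int, seed: int,
                             book: CostBook | None = None,
                             model: PriceModel | None = None,
                             retain_ledger: bool = True
                             ) -> list[ScenarioBundle]:
    """Generate ``n`` compartment bundles for ranking and oracle tests.

    Templates are cycled for ``n`` beyond six, with fresh per-bundle RNG
    streams, so larger suites vary by noise realization.
    """
    if n_compartments < 1:
        raise ValidationError("need at least one compartment")
    book = book or CostBook()
    model = model or PriceModel()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_compartments)
    bundles = []
    for i in range(n_compartments):
        template = _TEMPLATES[i % len(_TEMPLATES)]
        cfg = ScenarioConfig(seed=int(child_seeds[i] % (2 ** 31)), **template)
        trace = generate_trace(cfg)
        schedule = generate_schedule(cfg)
        obs = generate_crop_series(cfg)
        truth = (naive_daily_ledger(trace, book, schedule.n_changes)
                 if retain_ledger else None)
        bundles.append(ScenarioBundle(
            name=f"compartment-{i + 1:02d}", config=cfg, trace=trace,
            schedule=schedule, observations=obs, ledger_truth=truth,
            book=book, model=model))
    return bundles


def write_bundle(bundle: ScenarioBundle, out_dir) -> None:
    """Write a bundle's trace, schedule and observations as CSV files."""
    from pathlib import Path

    from .data_model import write_control_trace, write_crop_observations
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_control_trace(bundle.trace, out / "trace.csv")
    bundle.schedule.to_csv(out / "schedule.csv")
    write_crop_observations(bundle.observations, out / "observations.csv")
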