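import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from greenprofit.data_model import (
    ALLOWED_DENSITIES,
    ControlTrace,
    CostBook,
    CropObservation,
    CropObservationSeries,
    CultivationEvaluation,
    DensitySchedule,
    PriceModel,
    ValidationError,
    read_control_trace,
    read_evaluation,
    write_control_trace,
    write_evaluation_report,
)

from conftest import build_trace


def _trace_csv(path, drop=None, shuffle=False, n_days=2):
    idx = pd.date_range("2024-09-02", periods=288 * n_days, freq="5min",
                        tz="Europe/Amsterdam")
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "timestamp": [t.isoformat() for t in idx],
        "lamp_activation": rng.uniform(0, 100, len(idx)),
        "air_temperature": rng.uniform(18, 24, len(idx)),
        "pipe_temperature": rng.uniform(20, 50, len(idx)),
        "pump_running": True,
        "co2_dosing_cumulative": np.cumsum(rng.uniform(0, 1, len(idx))),
    })
    if drop is not None:
        df = df.drop(index=drop).reset_index(drop=True)
    if shuffle:
        df = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    df.to_csv(path, index=False)
    return path


class TestReadControlTrace:
    def test_well_formed_two_days(self, tmp_path):
        trace = read_control_trace(_trace_csv(tmp_path / "t.csv"))
        assert len(trace.data) == 576
        assert trace.duration_days == 2

    def test_single_missing_record_filled_locf(self, tmp_path, caplog):
        path = _trace_csv(tmp_path / "t.csv", drop=[100])
        with caplog.at_level("WARNING"):
            trace = read_control_trace(path)
        assert len(trace.data) == 576
        assert any("filled 1 missing" in r.message for r in caplog.records)
        # LOCF: the filled record repeats its predecessor's state values
        assert (trace.data["lamp_activation"].iloc[100]
                == trace.data["lamp_activation"].iloc[99])

    def test_gap_filling_keeps_co2_monotone(self, tmp_path):
        path = _trace_csv(tmp_path / "t.csv", drop=[50, 51, 52])
        trace = read_control_trace(path)
        co2 = trace.data["co2_dosing_cumulative"].to_numpy()
        assert np.all(np.diff(co2) >= 0)

    def test_out_of_order_timestamps_rejected(self, tmp_path):
        path = _trace_csv(tmp_path / "t.csv", shuffle=True)
        with pytest.raises(ValidationError, match="increasing"):
            read_control_trace(path)

    def test_gap_beyond_limit_rejected(self, tmp_path):
        path = _trace_csv(tmp_path / "t.csv", drop=list(range(100, 110)))
        with pytest.raises(ValidationError, match="gap"):
            read_control_trace(path)

    def test_missing_required_channel_rejected(self, tmp_path):
        path = _trace_csv(tmp_path / "t.csv")
        df = pd.read_csv(path).drop(columns=["lamp_activation"])
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="lamp_activation"):
            read_control_trace(path)

    def test_dialect_column_mapping(self, tmp_path):
        path = _trace_csv(tmp_path / "t.csv")
        df = pd.read_csv(path).rename(
            columns={"lamp_activation": "LampsActivationPercentage"})
        df.to_csv(path, index=False)
        trace = read_control_trace(
            path, dialect={"lamp_activation": "LampsActivationPercentage"})
        assert len(trace.data) == 576

    def test_round_trip_is_lossless(self, tmp_path):
        trace = read_control_trace(_trace_csv(tmp_path / "t.csv"))
        write_control_trace(trace, tmp_path / "out.csv")
        back = read_control_trace(tmp_path / "out.csv")
        pd.testing.assert_frame_equal(trace.data, back.data)

    def test_round_trip_across_dst_transition(self, tmp_path):
        # mixed +02:00/+01:00 offsets in one CSV parse and round-trip
        from greenprofit.synthetic_data import ScenarioConfig, generate_trace
        trace = generate_trace(ScenarioConfig(
            seed=1, duration_days=3, start_date="2024-10-26"))
        write_control_trace(trace, tmp_path / "dst.csv")
        back = read_control_trace(tmp_path / "dst.csv")
        pd.testing.assert_frame_equal(trace.data, back.data)


class TestControlTraceInvariants:
    def test_incomplete_day_rejected(self):
        with pytest.raises(ValidationError, match="expected"):
            idx = pd.date_range("2024-09-02", periods=300, freq="5min",
                                tz="UTC")
            ControlTrace(pd.DataFrame({
                "lamp_activation": 0.0, "air_temperature": 20.0,
                "pipe_temperature": np.nan, "pump_running": False,
                "co2_dosing_cumulative": 0.0}, index=idx))

    def test_activation_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="lamp_activation"):
            build_trace(1, lamp=np.full(288, 101.0))

    def test_dst_transition_day_is_complete(self):
        # the 25 h day when clocks fall back has 300 records
        idx = pd.date_range("2024-10-27", periods=300, freq="5min",
                            tz="Europe/Amsterdam")
        trace = ControlTrace(pd.DataFrame({
            "lamp_activation": 0.0, "air_temperature": 20.0,
            "pipe_temperature": np.nan, "pump_running": False,
            "co2_dosing_cumulative": 0.0}, index=idx))
        assert trace.duration_days == 1


class TestDensitySchedule:
    def test_constant_schedule(self):
        s = DensitySchedule([(1, 56)], duration_days=70)
        assert s.n_changes == 0
        assert np.all(s.daily_densities() == 56)

    def test_full_spacing_ladder(self):
        s = DensitySchedule([(1, 56), (20, 42), (40, 30), (55, 20)],
                            duration_days=70)
        assert s.n_changes == 3
        d = s.daily_densities()
        assert d[18] == 56 and d[19] == 42   # change effective on day 20
        assert d[-1] == 20

    @pytest.mark.parametrize("events,msg", [
        ([(1, 56), (20, 30), (40, 42)], "decrease"),
        ([(1, 42)], "initial density"),
        ([(2, 56)], "day 1"),
        ([(1, 56), (10, 50)], "allowed set"),
        ([(1, 56), (10, 42), (10, 30)], "strictly increasing"),
        ([(1, 56), (80, 42)], "beyond"),
    ])
    def test_invalid_schedules_rejected(self, events, msg):
        with pytest.raises(ValidationError, match=msg):
            DensitySchedule(events, duration_days=70)

    def test_n_changes_before(self):
        s = DensitySchedule([(1, 56), (20, 42), (40, 30)], duration_days=70)
        assert s.n_changes_before(19) == 0
        assert s.n_changes_before(20) == 1
        assert s.n_changes_before(70) == 2

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(ALLOWED_DENSITIES), min_size=1,
                    max_size=6),
           st.lists(st.integers(1, 70), min_size=1, max_size=6))
    def test_validator_accepts_exactly_valid_schedules(self, dens, days):
        n = min(len(dens), len(days))
        events = list(zip(sorted(days)[:n], dens[:n]))
        evdays = [d for d, _ in events]
        evdens = [x for _, x in events]
        valid = (evdays[0] == 1 and evdens[0] == 56
                 and all(b > a for a, b in zip(evdays, evdays[1:]))
                 and all(b < a for a, b in zip(evdens, evdens[1:]))
                 and len(events) <= 4)
        if valid:
            DensitySchedule(events, duration_days=70)
        else:
            with pytest.raises(ValidationError):
                DensitySchedule(events, duration_days=70)

    def test_csv_round_trip(self, tmp_path):
        s = DensitySchedule([(1, 56), (30, 30)], duration_days=60)
        s.to_csv(tmp_path / "s.csv")
        back = DensitySchedule.from_csv(tmp_path / "s.csv", 60)
        assert back.events == s.events


class TestCropObservations:
    def test_red_exceeding_total_flagged_not_rejected(self):
        obs = CropObservationSeries([
            CropObservation(40, 100, 50, 0.5, 6.5),
            CropObservation(70, 200, 202, 1.01, 6.5),
        ])
        assert any("red > total" in f for f in obs.flags)

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            CropObservationSeries([CropObservation(40, 100, 50, 0.5, 6.5),
                                   CropObservation(40, 120, 60, 0.5, 6.5)])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError, match=">= 0"):
            CropObservationSeries([CropObservation(40, -1, 0, 0, 6.5)])


class TestConfigsAndReports:
    def test_cost_book_yaml_round_trip(self, tmp_path):
        book = CostBook(on_peak_price=0.35, plant_cost=0.80)
        book.to_yaml(tmp_path / "book.yaml")
        assert CostBook.from_yaml(tmp_path / "book.yaml") == book

    def test_price_model_yaml_round_trip(self, tmp_path):
        model = PriceModel(price_low_at_cap=1.5)
        model.to_yaml(tmp_path / "pm.yaml")
        assert PriceModel.from_yaml(tmp_path / "pm.yaml") == model

    def test_negative_price_rejected(self):
        with pytest.raises(ValidationError):
            CostBook(heat_price=-0.01)
        with pytest.raises(ValidationError):
            PriceModel(ffw_min=200)  # >= cap

    def test_evaluation_report_round_trips(self, tmp_path):
        ev = CultivationEvaluation(
            team="X", duration_days=3, gains_per_pot=1.15,
            cost_per_pot=0.0133, net_profit=0.3456789, avg_density=56.0,
            annualized_yield=45.3,
            ledger=pd.DataFrame({"day": [1, 2, 3], "Ld": [0.1, 0.1, 0.1]}))
        paths = write_evaluation_report(ev, tmp_path)
        back = read_evaluation(paths["machine"])
        assert back.net_profit == ev.net_profit
        pd.testing.assert_frame_equal(back.ledger, ev.ledger)

    def test_summary_rounds_money_half_up(self, tmp_path):
        import json
        ev = CultivationEvaluation(
            team="X", duration_days=70, gains_per_pot=1.05,
            cost_per_pot=0.44, net_profit=0.345, avg_density=39.7)
        paths = write_evaluation_report(ev, tmp_path)
        summary = json.loads(paths["summary"].read_text())
        assert summary["net_profit"] == "0.35"   # half-up, not banker's

    def test_empty_ledger_rejected(self, tmp_path):
        ev = CultivationEvaluation(
            team="X", duration_days=1, gains_per_pot=1.0, cost_per_pot=0.1,
            net_profit=0.1, avg_density=56.0, ledger=pd.DataFrame())
        with pytest.raises(ValidationError, match="empty"):
            write_evaluation_report(ev, tmp_path)
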