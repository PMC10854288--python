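"""Compliance, session analysis orchestration, time-series reports, CLI."""

import json
from datetime import date

import numpy as np
import pytest
from click.testing import CliRunner

from digitap.cli import main as cli_main
from digitap.core import TraceMeta, write_trace
from digitap.detection import detect_strikes
from digitap.errors import ParameterError
from digitap.metrics import hand_metrics, per_finger_metrics, split_by_lever
from digitap.reporting import (
    MedicationEvent,
    SessionLog,
    TestRecord,
    analyze_session,
    compliance_ratio,
    timeseries_report,
)
from digitap.scoring import score_panel
from digitap.simulate import SimulationParams, control_params, simulate_trace
from digitap.tremor import classify_strikes, tremor_summary


def control_trace(seed=15, age=60.0):
    rng = np.random.default_rng(1000 + seed)
    params = control_params(age, rng)
    return simulate_trace(params, seed=seed,
                          meta=TraceMeta(subject_id="HC", age_years=age))[0]


class TestCompliance:
    def test_sixteen_days_in_a_thirty_day_month(self):
        stamps = [f"2024-04-{d:02d}T09:00:00+00:00" for d in range(1, 17)]
        c = compliance_ratio(stamps, 2024, 4)
        assert c.ratio == pytest.approx(16 / 30)
        assert c.monitoring_criterion_met

    def test_no_tests_is_zero(self):
        c = compliance_ratio([], 2024, 4)
        assert c.ratio == 0.0 and not c.monitoring_criterion_met

    def test_multiple_tests_on_one_day_count_once(self):
        stamps = ["2024-04-03T09:00:00+00:00", "2024-04-03T17:30:00+00:00"]
        c = compliance_ratio(stamps, 2024, 4)
        assert c.days_tested == 1

    def test_in_progress_month_counts_elapsed_days(self):
        stamps = [f"2024-04-{d:02d}T09:00:00+00:00" for d in range(1, 11)]
        c = compliance_ratio(stamps, 2024, 4, today=date(2024, 4, 10))
        assert c.days_possible == 10
        assert c.ratio == pytest.approx(1.0)

    def test_criterion_windows_span_months(self):
        # 16 distinct days split across a month boundary
        stamps = [f"2024-03-{d:02d}T08:00:00+00:00" for d in range(24, 32)] + [
            f"2024-04-{d:02d}T08:00:00+00:00" for d in range(1, 9)
        ]
        c = compliance_ratio(stamps, 2024, 4)
        assert c.monitoring_criterion_met

    def test_bad_month_rejected(self):
        with pytest.raises(ParameterError):
            compliance_ratio([], 2024, 13)
        with pytest.raises(ParameterError, match="not started"):
            compliance_ratio([], 2024, 6, today=date(2024, 5, 1))


class TestAnalyzeSession:
    def test_control_trace_scores_high_with_normal_flags(self, reference):
        res = analyze_session(control_trace(seed=15), reference)
        assert res.status == "ok"
        assert res.panel.mobility_score >= 90.0
        assert all(m.flag == "normal" for m in res.panel.metrics.values())
        assert res.panel.mobility_flag == "normal"

    def test_severe_bradykinesia_scores_low_and_flags_amplitude(self, reference):
        params = SimulationParams(
            base_amplitude_mm=2.0, isi_mean_s=1.1, press_duration_s=0.3,
            release_duration_s=0.35, dwell_s=0.25, isi_cv=0.25,
            amplitude_decay_per_tap=0.015, amplitude_jitter_cv=0.1,
        )
        trace, _ = simulate_trace(params, seed=7, meta=TraceMeta(age_years=65.0))
        res = analyze_session(trace, reference)
        assert res.status == "ok"
        assert res.panel.mobility_score < 50.0
        assert res.panel.metrics["press_amplitude_mm"].flag == "abnormal"

    def test_tremor_trace_keeps_mobility_but_scores_severity(self, reference):
        params = SimulationParams(tremor_pct_target=18.0, tremor_amplitude_mm=2.5)
        trace, _ = simulate_trace(params, seed=3, meta=TraceMeta(age_years=60.0))
        res = analyze_session(trace, reference)
        assert res.panel.rest_tremor_pct == pytest.approx(18.0, abs=1.5)
        assert res.panel.tremor_severity > res.panel.rest_tremor_pct
        assert res.panel.mobility_score >= 85.0

    def test_flat_trace_is_insufficient(self, reference, flat_trace):
        res = analyze_session(flat_trace, reference)
        assert res.status == "insufficient"
        assert res.hand_metrics is None and res.panel is None
        assert res.dashboard["status"] == "insufficient"

    def test_equals_composition_of_stage_calls(self, reference):
        trace = control_trace(seed=19)
        res = analyze_session(trace, reference)
        strikes = classify_strikes(detect_strikes(trace), trace)
        by = split_by_lever(strikes)
        hm = hand_metrics(
            per_finger_metrics(by["index"], trace.duration_s),
            per_finger_metrics(by["middle"], trace.duration_s),
            strikes, trace.duration_s,
        )
        ts = tremor_summary(strikes, trace.duration_s)
        panel = score_panel(hm, reference, age_years=trace.meta.age_years,
                            tremor_amplitudes_mm=ts.tremor_amplitudes_mm)
        assert res.hand_metrics == hm
        assert res.panel.mobility_score == panel.mobility_score
        assert res.panel.to_dict() == panel.to_dict()

    def test_dashboard_record_carries_panel_fields(self, reference):
        res = analyze_session(control_trace(seed=25), reference)
        dash = res.dashboard
        for field in ("taps_per_minute", "press_amplitude_mm", "press_speed_mm_s",
                      "press_amplitude_cv", "release_speed_mm_s", "rest_tremor_pct",
                      "arrhythmicity_pct", "mobility_score", "tremor_severity",
                      "flags", "therapy_state", "hand"):
            assert field in dash
        assert dash["arrhythmicity_pct"] == pytest.approx(
            100.0 * res.hand_metrics.isi_cv
        )


class TestTimeseries:
    def make_analyzed(self, reference, n_days=5):
        out = []
        for d in range(n_days):
            ts = f"2024-04-{d + 1:02d}T09:00:00+00:00"
            res = analyze_session(control_trace(seed=15), reference)
            out.append((ts, "R", res))
        return out

    def test_daily_sessions_give_one_point_per_day(self, reference):
        analyzed = self.make_analyzed(reference, 5)
        log = SessionLog(subject_id="S1")
        doc = timeseries_report(log, analyzed)
        assert len(doc["series"]["R"]["mobility_score"]) == 5
        assert doc["series"]["L"] == {}

    def test_dose_delta_in_minutes(self, reference):
        log = SessionLog(
            subject_id="S1",
            medications=[
                MedicationEvent("CD/LD", "25/100",
                                "2024-04-01T09:00:00+00:00",
                                "2024-04-01T09:25:00+00:00"),
            ],
        )
        doc = timeseries_report(log, self.make_analyzed(reference, 1))
        assert doc["medication_adherence"][0]["delta_minutes"] == pytest.approx(25.0)

    def test_missed_dose_listed_separately(self, reference):
        log = SessionLog(
            subject_id="S1",
            medications=[
                MedicationEvent("CD/LD", "25/100", "2024-04-01T09:00:00+00:00", None)
            ],
        )
        doc = timeseries_report(log, self.make_analyzed(reference, 1))
        assert doc["medication_adherence"] == []
        assert len(doc["missed_doses"]) == 1

    def test_no_sessions_rejected(self):
        with pytest.raises(ParameterError):
            timeseries_report(SessionLog(subject_id="x"), [])

    def test_naive_timestamp_rejected(self):
        with pytest.raises(ParameterError, match="timezone"):
            TestRecord("2024-04-01T09:00:00", "R")

    def test_session_log_json_round_trip(self, tmp_path):
        log = SessionLog(
            subject_id="S9",
            tests=[TestRecord("2024-04-01T09:00:00+00:00", "L", "t.tsv")],
            medications=[MedicationEvent("CD/LD", "25/100",
                                         "2024-04-01T08:00:00+00:00",
                                         "2024-04-01T08:10:00+00:00")],
            dbs_settings=["STN 130 Hz"],
            more_affected_hand="L",
        )
        p = tmp_path / "log.json"
        log.to_json(p)
        assert SessionLog.from_json(p) == log


class TestCli:
    def test_simulate_analyze_report_round_trip(self, tmp_path):
        runner = CliRunner()
        trace_path = tmp_path / "trace.tsv"
        gt_path = tmp_path / "truth.tsv"
        r = runner.invoke(cli_main, [
            "simulate", "--seed", "15", "--out", str(trace_path),
            "--ground-truth", str(gt_path),
        ])
        assert r.exit_code == 0, r.output
        assert trace_path.exists() and gt_path.exists()

        out = tmp_path / "session.json"
        r = runner.invoke(cli_main, ["analyze", str(trace_path), "--out", str(out)])
        assert r.exit_code == 0, r.output
        doc = json.loads(out.read_text())
        assert doc["status"] == "ok" and "mobility_score" in doc

        log = SessionLog(
            subject_id="S1",
            tests=[TestRecord("2024-04-01T09:00:00+00:00", "R", "trace.tsv")],
        )
        log_path = tmp_path / "log.json"
        log.to_json(log_path)
        rep = tmp_path / "report.json"
        r = runner.invoke(cli_main, [
            "report", "--log", str(log_path), "--month", "2024-04",
            "--out", str(rep),
        ])
        assert r.exit_code == 0, r.output
        doc = json.loads(rep.read_text())
        assert doc["compliance"]["days_tested"] == 1

    def test_build_reference_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ref.json"
        r = runner.invoke(cli_main, [
            "build-reference", "--n", "12", "--seed", "3", "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        doc = json.loads(out.read_text())
        assert doc["kind"] == "digitap-normative-reference"
        assert doc["synthetic"] is True

    def test_analyze_flat_trace_exits_3(self, tmp_path, flat_trace):
        trace_path = tmp_path / "flat.tsv"
        write_trace(flat_trace, trace_path)
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "analyze", str(trace_path), "--out", str(tmp_path / "o.json"),
        ])
        assert r.exit_code == 3

    def test_bad_simulation_config_exits_2(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({"isi_mean_s": 0.1}))  # pulses overlap
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "simulate", "--config", str(cfg), "--out", str(tmp_path / "t.tsv"),
        ])
        assert r.exit_code == 2
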