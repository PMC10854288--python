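"""Session analysis orchestration, compliance and time-series reports.

Mirrors the clinician dashboard as machine-readable JSON: a per-test
panel (metrics, flags, Mobility and Tremor Severity Scores, therapy
header), a monthly compliance ratio with the 16-of-30-days
remote-monitoring criterion, and a time-series view with medication
prescribed-versus-actual adherence deltas.  All reports are pure
functions of their inputs.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .core import RaftTrace, ScoringConstants, Strike
from .detection import DetectionConfig, alternation_report, detect_strikes
from .errors import ParameterError
from .metrics import HandMetrics, hand_metrics, per_finger_metrics, split_by_lever
from .scoring import NormativeReference, ScorePanel, score_panel
from .tremor import TremorClassifierSpec, classify_strikes, tremor_summary

REPORT_SCHEMA_VERSION = 1

#: minimum distinct test days in any 30-day window for the
#: remote-monitoring reimbursement criterion
MONITORING_MIN_DAYS = 16
MONITORING_WINDOW_DAYS = 30


# ---------------------------------------------------------------------
# Session logs
# ---------------------------------------------------------------------

def _parse_ts(value: str, *, require_tz: bool = True) -> datetime:
    try:
        ts = datetime.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"bad timestamp {value!r}") from exc
    if require_tz and ts.tzinfo is None:
        raise ParameterError(f"timestamp {value!r} must be timezone-aware")
    return ts


@dataclass
class TestRecord:
    __test__ = False  # not a pytest class despite the name

    timestamp: str  # ISO-8601, timezone-aware
    hand: str
    trace_path: str = ""

    def __post_init__(self):
        _parse_ts(self.timestamp)
        if self.hand not in ("L", "R"):
            raise ParameterError(f"hand must be L or R, got {self.hand!r}")


@dataclass
class MedicationEvent:
    """One dose: prescribed time and, if taken, the actual time."""

    name: str
    dose: str
    prescribed_time: str  # ISO-8601, timezone-aware
    actual_time: Optional[str] = None  # None = missed dose

    def __post_init__(self):
        _parse_ts(self.prescribed_time)
        if self.actual_time is not None:
            _parse_ts(self.actual_time)

    @property
    def delta_minutes(self) -> Optional[float]:
        """actual - prescribed, minutes (None when the dose was missed)."""
        if self.actual_time is None:
            return None
        d = _parse_ts(self.actual_time) - _parse_ts(self.prescribed_time)
        return d.total_seconds() / 60.0


@dataclass
class SessionLog:
    """Subject-level log of tests, medication events and therapy notes."""

    subject_id: str
    tests: List[TestRecord] = field(default_factory=list)
    medications: List[MedicationEvent] = field(default_factory=list)
    dbs_settings: List[str] = field(default_factory=list)
    more_affected_hand: Optional[str] = None

    def to_json(self, path) -> None:
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "more_affected_hand": self.more_affected_hand,
            "dbs_settings": self.dbs_settings,
            "tests": [
                {"timestamp": t.timestamp, "hand": t.hand, "trace_path": t.trace_path}
                for t in self.tests
            ],
            "medications": [
                {
                    "name": m.name, "dose": m.dose,
                    "prescribed_time": m.prescribed_time,
                    "actual_time": m.actual_time,
                }
                for m in self.medications
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "SessionLog":
        doc = json.loads(Path(path).read_text())
        return cls(
            subject_id=str(doc.get("subject_id", "")),
            tests=[TestRecord(**t) for t in doc.get("tests", [])],
            medications=[MedicationEvent(**m) for m in doc.get("medications", [])],
            dbs_settings=list(doc.get("dbs_settings", [])),
            more_affected_hand=doc.get("more_affected_hand"),
        )


# ---------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------

@dataclass
class ComplianceResult:
    ratio: float
    days_tested: int
    days_possible: int
    monitoring_criterion_met: bool  # >= 16 distinct test days in some 30-day window


def _to_date(ts) -> date:
    if isinstance(ts, datetime):
        return ts.date()
    if isinstance(ts, date):
        return ts
    return _parse_ts(str(ts), require_tz=False).date()


def compliance_ratio(
    test_timestamps: Sequence,
    year: int,
    month: int,
    today: Optional[date] = None,
) -> ComplianceResult:
    """Monthly testing compliance.

    ratio = distinct calendar days in (year, month) with at least one
    completed test, divided by the possible test days: the full month
    if it has passed, else the days elapsed through ``today``.  Also
    reports whether any 30-day window over all supplied timestamps
    contains at least 16 distinct test days (the remote-monitoring
    reimbursement criterion).
    """
    if not 1 <= month <= 12:
        raise ParameterError(f"bad month {month}")
    n_in_month = calendar.monthrange(year, month)[1]
    days = sorted({_to_date(t) for t in test_timestamps})
    month_days = [d for d in days if d.year == year and d.month == month]
    if today is None:
        possible = n_in_month
    else:
        today = _to_date(today)
        first = date(year, month, 1)
        if today < first:
            raise ParameterError("month has not started: no possible test days")
        possible = min(today.day, n_in_month) if (today.year, today.month) == (year, month) else n_in_month
    met = False
    window = timedelta(days=MONITORING_WINDOW_DAYS - 1)
    for d0 in days:
        if sum(1 for d in days if d0 <= d <= d0 + window) >= MONITORING_MIN_DAYS:
            met = True
            break
    return ComplianceResult(
        ratio=len(month_days) / possible,
        days_tested=len(month_days),
        days_possible=possible,
        monitoring_criterion_met=met,
    )


# ---------------------------------------------------------------------
# Single-session analysis
# ---------------------------------------------------------------------

@dataclass
class SessionResult:
    """Outcome of analyzing one trace.

    status "ok" carries metrics + scores; "insufficient" (fewer than
    two voluntary strikes on some finger — the redo-the-test case)
    carries neither.
    """

    status: str  # "ok" | "insufficient"
    hand_metrics: Optional[HandMetrics]
    panel: Optional[ScorePanel]
    strikes: List[Strike] = field(default_factory=list)
    dashboard: dict = field(default_factory=dict)


def _dashboard_record(
    trace: RaftTrace, hm: HandMetrics, panel: ScorePanel,
    compliance: Optional[ComplianceResult],
) -> dict:
    flags = {m: s.flag for m, s in panel.metrics.items()}
    rec = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "subject_id": trace.meta.subject_id,
        "session_timestamp": trace.meta.session_timestamp,
        "therapy_state": trace.meta.therapy_state,
        "hand": trace.hand,
        "taps_per_minute": hm.taps_per_minute,
        "press_amplitude_mm": hm.press_amplitude_mm,
        "press_speed_mm_s": hm.press_speed_mm_s,
        "press_amplitude_cv": hm.press_amplitude_cv,
        "release_speed_mm_s": hm.release_slope_mm_s,
        "dwell_time_s": hm.dwell_time_s,
        "rest_tremor_pct": hm.rest_tremor_pct,
        "arrhythmicity_pct": hm.arrhythmicity_pct,
        "mobility_score": panel.mobility_score,
        "mobility_flag": panel.mobility_flag,
        "tremor_severity": panel.tremor_severity,
        "mean_tremor_amplitude_mm": panel.mean_tremor_amplitude_mm,
        "flags": flags,
    }
    if compliance is not None:
        rec["compliance"] = {
            "ratio": compliance.ratio,
            "days_tested": compliance.days_tested,
            "days_possible": compliance.days_possible,
            "monitoring_criterion_met": compliance.monitoring_criterion_met,
        }
    return rec


def analyze_session(
    trace: RaftTrace,
    reference: NormativeReference,
    classifier: Optional[TremorClassifierSpec] = None,
    constants: Optional[ScoringConstants] = None,
    detection_config: Optional[DetectionConfig] = None,
    compliance: Optional[ComplianceResult] = None,
    suppression_mode: str = "scale",
) -> SessionResult:
    """Analyze one trace end to end: detection, tremor classification,
    metrics, scoring, dashboard record.

    Equals the composition of the stage functions called independently
    (no hidden state).  When a finger has fewer than two voluntary
    strikes the result has status "insufficient" with metrics and
    scores absent.
    """
    if constants is not None and constants != reference.constants:
        reference = NormativeReference(
            metrics=reference.metrics, constants=constants,
            n_subjects=reference.n_subjects, synthetic=reference.synthetic,
        )
    strikes = detect_strikes(trace, detection_config)
    strikes = classify_strikes(strikes, trace, classifier)
    by_lever = split_by_lever(strikes)
    fingers = {
        lever: per_finger_metrics(by_lever[lever], trace.duration_s)
        for lever in ("index", "middle")
    }
    if any(f.n_voluntary_strikes < 2 for f in fingers.values()):
        return SessionResult(
            status="insufficient", hand_metrics=None, panel=None, strikes=strikes,
            dashboard={
                "schema_version": REPORT_SCHEMA_VERSION,
                "subject_id": trace.meta.subject_id,
                "session_timestamp": trace.meta.session_timestamp,
                "hand": trace.hand,
                "status": "insufficient",
                "reason": "fewer than 2 voluntary strikes on a finger; redo the test",
            },
        )
    hm = hand_metrics(fingers["index"], fingers["middle"], strikes, trace.duration_s)
    ts = tremor_summary(strikes, trace.duration_s)
    panel = score_panel(
        hm, reference, age_years=trace.meta.age_years,
        tremor_amplitudes_mm=ts.tremor_amplitudes_mm,
        suppression_mode=suppression_mode,
    )
    dash = _dashboard_record(trace, hm, panel, compliance)
    dash["status"] = "ok"
    dash["alternation"] = {
        "same_lever_repeats": alternation_report(strikes).n_same_lever_repeats,
        "overlapping_presses": alternation_report(strikes).n_overlapping_presses,
    }
    return SessionResult(
        status="ok", hand_metrics=hm, panel=panel, strikes=strikes, dashboard=dash
    )


# ---------------------------------------------------------------------
# Time-series / medication report
# ---------------------------------------------------------------------

#: dashboard fields included in the per-day series
_SERIES_FIELDS = (
    "mobility_score", "tremor_severity", "taps_per_minute",
    "press_amplitude_mm", "press_speed_mm_s", "press_amplitude_cv",
    "release_speed_mm_s", "rest_tremor_pct", "arrhythmicity_pct",
)


def timeseries_report(
    log: SessionLog,
    analyzed: Sequence[Tuple[str, str, SessionResult]],
    window_days: int = 30,
) -> dict:
    """Chronological per-hand metric series plus medication adherence.

    ``analyzed`` pairs each test (timestamp, hand) with its
    :class:`SessionResult`; insufficient sessions are listed but carry
    no values.  Adherence deltas are actual minus prescribed dose time
    in minutes; missed doses (no actual time) are listed separately.
    """
    if not analyzed:
        raise ParameterError("need at least one analyzed session")
    cutoff = max(_parse_ts(ts) for ts, _, _ in analyzed) - timedelta(days=window_days)
    series: Dict[str, Dict[str, list]] = {"L": {}, "R": {}}
    insufficient = []
    for ts, hand, result in sorted(analyzed, key=lambda r: _parse_ts(r[0])):
        when = _parse_ts(ts)
        if when < cutoff:
            continue
        if result.status != "ok":
            insufficient.append({"timestamp": ts, "hand": hand})
            continue
        dash = result.dashboard
        flags = dash.get("flags", {})
        for name in _SERIES_FIELDS:
            flag = {
                "mobility_score": dash.get("mobility_flag"),
                "press_amplitude_mm": flags.get("press_amplitude_mm"),
                "press_speed_mm_s": flags.get("press_speed_mm_s"),
                "press_amplitude_cv": flags.get("press_amplitude_cv"),
                "release_speed_mm_s": flags.get("release_slope_mm_s"),
                "taps_per_minute": flags.get("taps_per_minute"),
                "arrhythmicity_pct": flags.get("isi_cv"),
            }.get(name)
            series[hand].setdefault(name, []).append(
                {"timestamp": ts, "value": dash.get(name), "flag": flag}
            )
    adherence = []
    missed = []
    for m in log.medications:
        entry = {"name": m.name, "dose": m.dose, "prescribed_time": m.prescribed_time}
        if m.actual_time is None:
            missed.append(entry)
        else:
            adherence.append(
                {**entry, "actual_time": m.actual_time, "delta_minutes": m.delta_minutes}
            )
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "subject_id": log.subject_id,
        "more_affected_hand": log.more_affected_hand,
        "dbs_settings": log.dbs_settings,
        "window_days": window_days,
        "series": series,
        "insufficient_sessions": insufficient,
        "medication_adherence": adherence,
        "missed_doses": missed,
    }
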