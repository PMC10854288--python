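"""Domain types and trace file I/O.

A repetitive alternating finger-tapping (RAFT) record is a pair of lever
displacement time series (index and middle finger) sampled at a fixed
rate for nominally 30 s.  Displacement is in millimetres, time in
seconds, 0-based from trace start.  Files are long-format tab-separated
text with a single JSON header line carrying the sample rate and
session metadata, so a trace is fully self-describing and diff-able.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ParameterError, TraceFormatError, TraceValidationError

LEVERS = ("index", "middle")

#: tolerance on sample spacing, seconds
_TIME_TOL = 1e-6

#: decimal places written to trace files (declared precision of the format)
_FILE_DECIMALS = 6

TRACE_SCHEMA_VERSION = 1


@dataclass
class TraceMeta:
    """Session metadata carried with a trace."""

    subject_id: str = ""
    session_timestamp: str = ""  # ISO-8601 if present
    therapy_state: str = ""  # free text, e.g. "off meds", "DBS on"
    age_years: Optional[float] = None

    def validate(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise TraceValidationError(f"negative age: {self.age_years}")


@dataclass
class RaftTrace:
    """Two-lever displacement record for one hand and session.

    Attributes
    ----------
    sample_rate_hz : float
        Sampling rate, Hz (> 0).
    time_s : ndarray
        Sample times, strictly increasing, spacing 1/sample_rate_hz.
    displacement_mm : dict[str, ndarray]
        One series per lever ("index", "middle"), equal length, >= 0.
    hand : str
        "L" or "R".
    meta : TraceMeta
    """

    sample_rate_hz: float
    time_s: np.ndarray
    displacement_mm: dict
    hand: str = "R"
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = {
            k: np.asarray(v, dtype=float) for k, v in self.displacement_mm.items()
        }
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self, amp_max_mm: Optional[float] = None) -> None:
        if not (self.sample_rate_hz > 0 and math.isfinite(self.sample_rate_hz)):
            raise TraceValidationError(f"bad sample rate {self.sample_rate_hz}")
        if self.hand not in ("L", "R"):
            raise TraceValidationError(f"hand must be 'L' or 'R', got {self.hand!r}")
        if set(self.displacement_mm) != set(LEVERS):
            raise TraceValidationError(
                f"levers must be exactly {LEVERS}, got {sorted(self.displacement_mm)}"
            )
        n = self.time_s.size
        if n == 0:
            raise TraceValidationError("empty trace")
        for lever, d in self.displacement_mm.items():
            if d.size != n:
                raise TraceValidationError(
                    f"lever {lever!r} has {d.size} samples, time axis has {n}"
                )
            if not np.all(np.isfinite(d)):
                raise TraceValidationError(f"non-finite displacement on {lever!r}")
            if np.any(d < 0):
                raise TraceValidationError(f"negative displacement on {lever!r}")
            if amp_max_mm is not None and np.any(d > amp_max_mm + 1e-9):
                raise TraceValidationError(
                    f"displacement on {lever!r} exceeds amp_max {amp_max_mm} mm"
                )
        dt = np.diff(self.time_s)
        if n > 1:
            if np.any(dt <= 0):
                raise TraceValidationError("time not strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate_hz) > _TIME_TOL):
                raise TraceValidationError(
                    "sample spacing inconsistent with declared rate"
                )
        if self.duration_s < 1.0 - _TIME_TOL:
            raise TraceValidationError(
                f"trace shorter than 1 s ({self.duration_s:.3f} s)"
            )
        self.meta.validate()

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        """Duration including the final sample interval."""
        return float(self.time_s.size / self.sample_rate_hz)

    def shifted(self, offset_s: float) -> "RaftTrace":
        """Copy with all sample times shifted by ``offset_s`` (>= 0 start)."""
        t = self.time_s + offset_s
        if t[0] < 0:
            raise ParameterError("shift would produce negative times")
        return replace(self, time_s=t, displacement_mm=dict(self.displacement_mm))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RaftTrace):
            return NotImplemented
        return (
            self.sample_rate_hz == other.sample_rate_hz
            and self.hand == other.hand
            and self.meta == other.meta
            and np.array_equal(self.time_s, other.time_s)
            and all(
                np.array_equal(self.displacement_mm[k], other.displacement_mm[k])
                for k in LEVERS
            )
        )


@dataclass
class Strike:
    """One detected press/release cycle on one lever.

    Phase times (seconds, trace clock): press onset < press bottom <=
    release onset < release end.  Dwell is the hold at the bottom of the
    press; durations are differences of the phase times.
    """

    lever: str
    t_press_onset: float
    t_press_bottom: float
    t_release_onset: float
    t_release_end: float
    press_amplitude_mm: float
    release_amplitude_mm: float
    is_tremor: bool = False

    def __post_init__(self):
        if self.lever not in LEVERS:
            raise TraceValidationError(f"unknown lever {self.lever!r}")
        if not (
            self.t_press_onset
            < self.t_press_bottom
            <= self.t_release_onset
            < self.t_release_end
        ):
            raise TraceValidationError(
                "strike phases out of order: "
                f"{self.t_press_onset}, {self.t_press_bottom}, "
                f"{self.t_release_onset}, {self.t_release_end}"
            )
        if self.press_amplitude_mm < 0 or self.release_amplitude_mm < 0:
            raise TraceValidationError("negative strike amplitude")

    @property
    def press_duration_s(self) -> float:
        return self.t_press_bottom - self.t_press_onset

    @property
    def dwell_time_s(self) -> float:
        return self.t_release_onset - self.t_press_bottom

    @property
    def release_duration_s(self) -> float:
        return self.t_release_end - self.t_release_onset

    @property
    def duration_s(self) -> float:
        """Full cycle duration, onset to release end."""
        return self.t_release_end - self.t_press_onset

    @property
    def press_speed_mm_s(self) -> float:
        return self.press_amplitude_mm / self.press_duration_s

    @property
    def release_slope_mm_s(self) -> float:
        return self.release_amplitude_mm / self.release_duration_s


@dataclass(frozen=True)
class ScoringConstants:
    """Constants of the Mobility and Tremor Severity score formulas.

    ``amp_max_mm`` is the maximum possible lever displacement of the
    device (the tremor-amplitude normalizer).  It is not published for
    the device; the default 12.5 mm is back-computed from a printed
    worked example (severity 41 at 18% tremor with 5.7 mm mean
    amplitude) and is configurable.
    """

    amp_max_mm: float = 12.5
    reference_age_years: float = 60.0
    mobility_scale: float = 14.0
    mobility_n: int = 6
    pa_transform_A: float = 3.2
    pa_transform_k: float = 0.495
    pa_z_transition: float = 10.0
    pa_z_cap: float = 20.0
    rt_A: float = 4.0
    rt_k: float = 0.05
    rt_b: float = -1.0
    low_tremor_pct_threshold: float = 10.0

    def __post_init__(self):
        for name in (
            "amp_max_mm",
            "reference_age_years",
            "mobility_scale",
            "mobility_n",
            "pa_transform_A",
            "pa_transform_k",
            "pa_z_transition",
            "pa_z_cap",
            "rt_A",
            "rt_k",
            "low_tremor_pct_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "amp_max_mm": self.amp_max_mm,
            "reference_age_years": self.reference_age_years,
            "mobility_scale": self.mobility_scale,
            "mobility_n": self.mobility_n,
            "pa_transform_A": self.pa_transform_A,
            "pa_transform_k": self.pa_transform_k,
            "pa_z_transition": self.pa_z_transition,
            "pa_z_cap": self.pa_z_cap,
            "rt_A": self.rt_A,
            "rt_k": self.rt_k,
            "rt_b": self.rt_b,
            "low_tremor_pct_threshold": self.low_tremor_pct_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConstants":
        return cls(**d)


# ---------------------------------------------------------------------
# Trace file I/O
# ---------------------------------------------------------------------

def write_trace(trace: RaftTrace, path) -> None:
    """Write a trace as long-format TSV with a JSON header line.

    Line 1 is ``# {json}`` holding schema version, sample rate, hand and
    metadata; line 2 the column header ``time_s\\tlever\\tdisplacement_mm``;
    then one row per (sample, lever).  Numeric fields are written at six
    decimal places, the declared precision of the format.
    """
    trace.validate()
    header = {
        "schema_version": TRACE_SCHEMA_VERSION,
        "sample_rate_hz": trace.sample_rate_hz,
        "hand": trace.hand,
        "subject_id": trace.meta.subject_id,
        "session_timestamp": trace.meta.session_timestamp,
        "therapy_state": trace.meta.therapy_state,
        "age_years": None if trace.meta.age_years is None else float(trace.meta.age_years),
        "units": {"time": "s", "displacement": "mm"},
    }
    path = Path(path)
    fmt = f"%.{_FILE_DECIMALS}f"
    try:
        with path.open("w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            fh.write("time_s\tlever\tdisplacement_mm\n")
            for lever in LEVERS:
                d = trace.displacement_mm[lever]
                for t, x in zip(trace.time_s, d):
                    fh.write(f"{fmt % t}\t{lever}\t{fmt % x}\n")
    except OSError as exc:
        raise TraceFormatError(f"cannot write {path}: {exc}") from exc


def read_trace(path, sample_rate_hz: Optional[float] = None) -> RaftTrace:
    """Read a trace file written by :func:`write_trace`.

    The file is validated, never repaired: missing columns raise
    :class:`TraceFormatError`; invariant violations (non-monotone time,
    negative displacement, >2 lever labels) raise
    :class:`TraceValidationError`.  ``sample_rate_hz`` overrides the
    header value and is required when the header lacks one.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such file: {path}")
    with path.open() as fh:
        first = fh.readline()
        header: dict = {}
        if first.startswith("#"):
            try:
                header = json.loads(first.lstrip("#").strip())
            except json.JSONDecodeError as exc:
                raise TraceFormatError(f"bad JSON header in {path}: {exc}") from exc
            colline = fh.readline()
        else:
            colline = first
        cols = colline.rstrip("\n").split("\t")
        required = {"time_s", "lever", "displacement_mm"}
        if not required.issubset(cols):
            raise TraceFormatError(
                f"missing columns {sorted(required - set(cols))} in {path}"
            )
        it, il, id_ = (cols.index(c) for c in ("time_s", "lever", "displacement_mm"))
        times: dict = {}
        disps: dict = {}
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                t, lever, x = float(parts[it]), parts[il], float(parts[id_])
            except (ValueError, IndexError) as exc:
                raise TraceFormatError(f"{path}:{lineno}: bad row") from exc
            times.setdefault(lever, []).append(t)
            disps.setdefault(lever, []).append(x)
    if len(times) > 2:
        raise TraceValidationError(
            f"more than two lever labels in {path}: {sorted(times)}"
        )
    rate = sample_rate_hz if sample_rate_hz is not None else header.get("sample_rate_hz")
    if rate is None:
        raise TraceFormatError(f"{path}: sample rate neither in header nor supplied")
    lever_times = {k: np.asarray(v) for k, v in times.items()}
    ref = next(iter(lever_times.values()), None)
    for k, v in lever_times.items():
        if ref is not None and (v.size != ref.size or not np.array_equal(v, ref)):
            raise TraceValidationError(f"{path}: lever time axes differ")
    meta = TraceMeta(
        subject_id=str(header.get("subject_id", "")),
        session_timestamp=str(header.get("session_timestamp", "")),
        therapy_state=str(header.get("therapy_state", "")),
        age_years=header.get("age_years"),
    )
    return RaftTrace(
        sample_rate_hz=float(rate),
        time_s=ref if ref is not None else np.array([]),
        displacement_mm={k: np.asarray(v) for k, v in disps.items()},
        hand=str(header.get("hand", "R")),
        meta=meta,
    )


def write_strikes(strikes, path) -> None:
    """Export strikes as a TSV annotation file, one row per strike."""
    cols = (
        "lever t_press_onset t_press_bottom t_release_onset t_release_end "
        "press_amplitude_mm release_amplitude_mm press_duration_s "
        "dwell_time_s release_duration_s is_tremor"
    ).split()
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in strikes:
            fh.write(
                f"{s.lever}\t{s.t_press_onset:.6f}\t{s.t_press_bottom:.6f}\t"
                f"{s.t_release_onset:.6f}\t{s.t_release_end:.6f}\t"
                f"{s.press_amplitude_mm:.6f}\t{s.release_amplitude_mm:.6f}\t"
                f"{s.press_duration_s:.6f}\t{s.dwell_time_s:.6f}\t"
                f"{s.release_duration_s:.6f}\t{int(s.is_tremor)}\n"
            )
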