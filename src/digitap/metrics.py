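"""Kinematic tapping metrics.

Eight metrics are computed per finger over *voluntary* strikes only
(tremor strikes are excluded before averaging) and then averaged,
unweighted, across the two fingers of a hand:

1. press amplitude (mm)          5. release slope (mm/s)
2. press amplitude CV            6. press speed (mm/s)
3. inter-strike interval, ISI (s)  7. dwell time (s)
4. ISI CV ("arrhythmicity")      8. rest tremor % of trace duration

plus taps per minute.  The ISI of a finger is the interval between its
successive voluntary press onsets — the time to complete one cycle of
that finger's movement.  CVs use the sample (n-1) standard deviation.
A finger with fewer than two voluntary strikes yields an all-absent
record (``None`` fields); absence propagates through hand averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Strike
from .errors import ParameterError


@dataclass
class FingerMetrics:
    """Per-finger metric means (``None`` = undefined)."""

    lever: str
    press_amplitude_mm: Optional[float] = None
    press_amplitude_cv: Optional[float] = None
    isi_s: Optional[float] = None
    isi_cv: Optional[float] = None
    press_speed_mm_s: Optional[float] = None
    release_slope_mm_s: Optional[float] = None
    dwell_time_s: Optional[float] = None
    n_voluntary_strikes: int = 0
    n_tremor_strikes: int = 0


@dataclass
class HandMetrics:
    """Hand-level metric record (finger averages + trace-level rates)."""

    press_amplitude_mm: Optional[float] = None
    press_amplitude_cv: Optional[float] = None
    isi_s: Optional[float] = None
    isi_cv: Optional[float] = None
    press_speed_mm_s: Optional[float] = None
    release_slope_mm_s: Optional[float] = None
    dwell_time_s: Optional[float] = None
    rest_tremor_pct: float = 0.0
    taps_per_minute: float = 0.0
    n_voluntary_strikes: int = 0
    n_tremor_strikes: int = 0

    @property
    def arrhythmicity_pct(self) -> Optional[float]:
        """ISI CV expressed in percent (the dashboard's 'Arrhythmicity')."""
        return None if self.isi_cv is None else 100.0 * self.isi_cv

    @property
    def complete(self) -> bool:
        """True when every metric is defined."""
        return all(
            getattr(self, f) is not None
            for f in (
                "press_amplitude_mm", "press_amplitude_cv", "isi_s", "isi_cv",
                "press_speed_mm_s", "release_slope_mm_s", "dwell_time_s",
            )
        )

    def to_dict(self) -> dict:
        return {
            "press_amplitude_mm": self.press_amplitude_mm,
            "press_amplitude_cv": self.press_amplitude_cv,
            "isi_s": self.isi_s,
            "isi_cv": self.isi_cv,
            "press_speed_mm_s": self.press_speed_mm_s,
            "release_slope_mm_s": self.release_slope_mm_s,
            "dwell_time_s": self.dwell_time_s,
            "rest_tremor_pct": self.rest_tremor_pct,
            "taps_per_minute": self.taps_per_minute,
            "n_voluntary_strikes": self.n_voluntary_strikes,
            "n_tremor_strikes": self.n_tremor_strikes,
        }


def _cv(values: np.ndarray) -> Optional[float]:
    """Sample-SD coefficient of variation; None below two values."""
    if values.size < 2:
        return None
    m = values.mean()
    if m == 0:
        return None
    return float(values.std(ddof=1) / m)


def per_finger_metrics(
    strikes: Sequence[Strike], trace_duration_s: Optional[float] = None
) -> FingerMetrics:
    """Average the kinematics of one lever's strikes.

    ``strikes`` must be time-ordered and single-lever with tremor flags
    already assigned; only voluntary strikes enter the averages.
    """
    levers = {s.lever for s in strikes}
    if len(levers) > 1:
        raise ParameterError(f"strikes span multiple levers: {sorted(levers)}")
    lever = levers.pop() if levers else "index"
    vol = [s for s in strikes if not s.is_tremor]
    n_trem = len(strikes) - len(vol)
    fm = FingerMetrics(lever=lever, n_voluntary_strikes=len(vol), n_tremor_strikes=n_trem)
    if len(vol) < 2:
        return fm
    amps = np.array([s.press_amplitude_mm for s in vol])
    onsets = np.array([s.t_press_onset for s in vol])
    isis = np.diff(onsets)
    # an interval spanning a pause (e.g. a tremor episode) is not a
    # movement cycle: drop intervals far beyond the typical cycle
    if isis.size >= 3:
        keep = isis <= 2.5 * np.median(isis)
        if keep.sum() >= 2:
            isis = isis[keep]
    fm.press_amplitude_mm = float(amps.mean())
    fm.press_amplitude_cv = _cv(amps)
    fm.isi_s = float(isis.mean())
    fm.isi_cv = _cv(isis)
    fm.press_speed_mm_s = float(np.mean([s.press_speed_mm_s for s in vol]))
    fm.release_slope_mm_s = float(np.mean([s.release_slope_mm_s for s in vol]))
    fm.dwell_time_s = float(np.mean([s.dwell_time_s for s in vol]))
    return fm


def _mean2(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return (a + b) / 2.0


def hand_metrics(
    index: FingerMetrics,
    middle: FingerMetrics,
    strikes: Sequence[Strike],
    trace_duration_s: float,
) -> HandMetrics:
    """Combine two finger records into the hand-level record.

    Each kinematic metric is the unweighted mean of the two finger
    values (an absent finger makes the hand value absent, mirroring
    symmetric averaging).  Rest tremor % is the summed duration of
    tremor strikes over the trace duration; taps/min counts voluntary
    strikes of both fingers.
    """
    if trace_duration_s <= 0:
        raise ParameterError("trace duration must be positive")
    n_vol = index.n_voluntary_strikes + middle.n_voluntary_strikes
    n_trem = index.n_tremor_strikes + middle.n_tremor_strikes
    tremor_time = sum(s.duration_s for s in strikes if s.is_tremor)
    return HandMetrics(
        press_amplitude_mm=_mean2(index.press_amplitude_mm, middle.press_amplitude_mm),
        press_amplitude_cv=_mean2(index.press_amplitude_cv, middle.press_amplitude_cv),
        isi_s=_mean2(index.isi_s, middle.isi_s),
        isi_cv=_mean2(index.isi_cv, middle.isi_cv),
        press_speed_mm_s=_mean2(index.press_speed_mm_s, middle.press_speed_mm_s),
        release_slope_mm_s=_mean2(index.release_slope_mm_s, middle.release_slope_mm_s),
        dwell_time_s=_mean2(index.dwell_time_s, middle.dwell_time_s),
        rest_tremor_pct=float(100.0 * tremor_time / trace_duration_s),
        taps_per_minute=float(60.0 * n_vol / trace_duration_s),
        n_voluntary_strikes=n_vol,
        n_tremor_strikes=n_trem,
    )


def split_by_lever(strikes: Sequence[Strike]) -> dict:
    """Partition an ordered strike list into per-lever ordered lists."""
    out: dict = {"index": [], "middle": []}
    for s in strikes:
        out[s.lever].append(s)
    return out
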