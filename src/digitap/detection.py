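"""Press/release cycle detection on lever displacement signals.

Each lever is processed independently.  The signal is lightly smoothed
(centered moving average), press segments are found by hysteresis
thresholding, and each segment is decomposed into four phase times:

* ``press onset`` — start of downward lever motion, found by walking
  back from the upward threshold crossing to the local start of motion;
* ``press bottom`` — first time the lever comes to rest at the bottom
  of the press: |velocity| falls below
  ``bottom_velocity_epsilon_mm_s`` within the top-amplitude region;
* ``release onset`` — last such at-rest time before the release;
* ``release end`` — the local minimum reached after the downward
  threshold crossing.

All four times are then refined to sub-sample precision by fitting the
press and release flanks with a raised-cosine stroke model (see
``_fit_flank``), falling back to interpolated velocity-epsilon
crossings and finally to the grid estimates, so phase durations are
not quantized to the sample grid.  Incomplete cycles touching the
trace boundaries are dropped.  A press with no at-rest sample (sharp
triangular peak) gets bottom = release onset = the displacement peak
(zero dwell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .core import LEVERS, RaftTrace, Strike
from .errors import ParameterError


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the cycle detector.

    All defaults are in physical units so behaviour is independent of
    the sampling rate.
    """

    smoothing_window_s: float = 0.02
    press_onset_threshold_mm: float = 0.3
    hysteresis_mm: float = 0.15
    min_cycle_duration_s: float = 0.05
    bottom_velocity_epsilon_mm_s: float = 2.0
    #: fraction of segment peak amplitude defining the "top region"
    #: searched for at-rest samples
    top_region_fraction: float = 0.85

    def __post_init__(self):
        for name in (
            "smoothing_window_s",
            "press_onset_threshold_mm",
            "hysteresis_mm",
            "min_cycle_duration_s",
            "bottom_velocity_epsilon_mm_s",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.hysteresis_mm >= self.press_onset_threshold_mm:
            raise ParameterError("hysteresis must be below the onset threshold")
        if not 0 < self.top_region_fraction < 1:
            raise ParameterError("top_region_fraction must be in (0, 1)")

    def scaled(self, factor: float) -> "DetectionConfig":
        """Config with amplitude thresholds scaled by ``factor`` (the
        detector is then equivariant to scaling the signal by the same
        factor)."""
        return DetectionConfig(
            smoothing_window_s=self.smoothing_window_s,
            press_onset_threshold_mm=self.press_onset_threshold_mm * factor,
            hysteresis_mm=self.hysteresis_mm * factor,
            min_cycle_duration_s=self.min_cycle_duration_s,
            bottom_velocity_epsilon_mm_s=self.bottom_velocity_epsilon_mm_s * factor,
            top_region_fraction=self.top_region_fraction,
        )


def moving_average(x: np.ndarray, window_s: float, sample_rate_hz: float) -> np.ndarray:
    """Centered moving average; window rounded to an odd sample count."""
    w = max(1, int(round(window_s * sample_rate_hz)))
    if w % 2 == 0:
        w += 1
    if w == 1 or x.size < w:
        return x.astype(float)
    kernel = np.ones(w) / w
    sm = np.convolve(x, kernel, mode="same")
    # repair edge bias of 'same' convolution with explicit partial means
    half = w // 2
    for i in range(half):
        sm[i] = x[: i + half + 1].mean()
        sm[-(i + 1)] = x[-(i + half + 1):].mean()
    return sm


def _segments_above(s: np.ndarray, hi: float, lo: float) -> List[tuple]:
    """Hysteresis segmentation: a segment opens when s rises to >= hi and
    closes when s falls to <= lo.  Returns (start, end) index pairs where
    start is the first sample >= hi and end the first sample <= lo after
    it (or len(s) if the signal never falls back)."""
    segs = []
    pressed = s[0] >= hi
    start = 0 if pressed else -1
    opened_at_start = pressed
    for i in range(1, s.size):
        if not pressed and s[i] >= hi:
            pressed, start = True, i
        elif pressed and s[i] <= lo:
            segs.append((start, i, opened_at_start, False))
            pressed = False
            opened_at_start = False
    if pressed:
        segs.append((start, s.size - 1, opened_at_start, True))
    return segs


def _walk_back_to_onset(s: np.ndarray, i: int, floor: int, level=None) -> int:
    """From crossing index ``i`` walk back to the local start of motion:
    descend to the near-baseline ``level`` (if given), then follow the
    monotone rise to its earliest sample."""
    j = i
    if level is not None:
        while j > floor and s[j] > level:
            j -= 1
    while j > floor and s[j - 1] < s[j]:
        j -= 1
    return j


def _walk_forward_to_end(s: np.ndarray, i: int, ceil_: int, level=None) -> int:
    """From the downward crossing walk forward to the local minimum
    (descending first to ``level`` when given, for noise robustness)."""
    j = i
    if level is not None:
        while j < ceil_ and s[j] > level:
            j += 1
    while j < ceil_ and s[j + 1] < s[j]:
        j += 1
    return j


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, eps: float) -> float:
    """Time where |v| crosses eps between (t0, v0) and (t1, v1), with
    |v0| > eps >= |v1|, by linear interpolation of |v|."""
    a0, a1 = abs(v0), abs(v1)
    if a0 == a1:
        return t1
    frac = (a0 - eps) / (a0 - a1)
    return t0 + frac * (t1 - t0)


def _fit_flank(t: np.ndarray, x: np.ndarray, base: float, plateau: float,
               band_lo: float, beta: float = 1.0):
    """Sub-sample boundary times of one movement flank.

    A smooth ballistic stroke between two rest levels is well modelled
    by a raised-cosine displacement flank (cosine-bell velocity, the
    standard smooth-stroke profile), for which
    ``arccos(1 - 2 * (x - base) / amplitude)`` is exactly linear in
    time.  A variance-weighted line through the mid-flank samples (the
    fractional-amplitude band [band_lo, 1 - band_lo], where the arccos
    is well conditioned) therefore yields the times the flank leaves
    one rest level (y = 0) and reaches the other (y = pi) at precision
    far below the sample grid.  ``beta`` < 1 undoes the known
    attenuation a centered moving average applies to the cosine
    component when the fit runs on the smoothed signal.  Returns
    (t_at_base, t_at_plateau) or None when the fit is infeasible.
    """
    amp = plateau - base
    if amp <= 0 or x.size < 3:
        return None
    c = (1.0 - 2.0 * (x - base) / amp) / beta
    m = (np.abs(c) < 1.0 - 2.0 * band_lo)
    if m.sum() < 2:
        return None
    cm = c[m]
    y = np.arccos(cm)
    w = np.sqrt(1.0 - cm * cm) + 0.05  # ~1/sigma of each y sample
    slope, icept = np.polyfit(t[m], y, 1, w=w)
    if slope == 0:
        return None
    t_y0 = -icept / slope
    t_ypi = (np.pi - icept) / slope
    return (t_y0, t_ypi)


def _box_beta(window_s: float, flank_T: float) -> float:
    """Attenuation of a cosine flank of duration ``flank_T`` by a
    centered moving average of width ``window_s`` (boxcar sinc)."""
    if flank_T <= 0 or window_s <= 0:
        return 1.0
    a = np.pi * window_s / (2.0 * flank_T)
    return float(np.sin(a) / a) if a > 1e-9 else 1.0


def _flank_times(t, x, s, base, plateau, band_lo, rel_noise, window_s):
    """Best flank-boundary estimate: raw-signal fit at low noise, else a
    two-pass fit on the smoothed signal with the boxcar attenuation of
    the cosine component corrected analytically."""
    if rel_noise <= 0.012:
        return _fit_flank(t, x, base, plateau, band_lo)
    first = _fit_flank(t, s, base, plateau, band_lo)
    if first is None:
        return _fit_flank(t, x, base, plateau, band_lo)
    beta = _box_beta(window_s, abs(first[1] - first[0]))
    refined = _fit_flank(t, s, base, plateau, band_lo, beta=beta)
    return refined if refined is not None else first


def _detect_lever(
    t: np.ndarray, x: np.ndarray, rate: float, cfg: DetectionConfig, lever: str
) -> List[Strike]:
    s = moving_average(x, cfg.smoothing_window_s, rate)
    dt = 1.0 / rate
    v = np.gradient(s, dt)
    hi = cfg.press_onset_threshold_mm
    lo = hi - cfg.hysteresis_mm
    eps = cfg.bottom_velocity_epsilon_mm_s
    # robust noise scale from the smoothing residual
    sigma = 1.4826 * float(np.median(np.abs(x - s))) if x.size > 2 else 0.0
    strikes: List[Strike] = []
    prev_end = 0
    w = max(1, int(round(cfg.smoothing_window_s * rate)))
    window_s = (w + 1 if w % 2 == 0 else w) * dt
    for seg_start, seg_end, at_start, at_end in _segments_above(s, hi, lo):
        if at_start or at_end:
            prev_end = seg_end  # partial cycle at a boundary: drop
            continue
        # baseline from the below-threshold samples of the preceding gap
        gap_lo = max(prev_end, seg_start - int(round(0.5 * rate)))
        gap = slice(gap_lo, seg_start + 1)
        low_mask = s[gap] < lo
        base = float(np.median(x[gap][low_mask])) if low_mask.any() else float(np.min(s[gap]))
        peak_idx = seg_start + int(np.argmax(s[seg_start : seg_end + 1]))
        amp_est = s[peak_idx] - base
        if amp_est <= cfg.press_onset_threshold_mm:
            continue
        near_base = base + max(0.04 * amp_est, 3.0 * sigma)
        onset = _walk_back_to_onset(s, seg_start, prev_end, level=near_base)
        end = _walk_forward_to_end(s, seg_end, s.size - 1, level=near_base)
        # pin to the local minima so a neighbouring pulse in a short
        # same-lever gap cannot leak into the flank-fit windows
        onset = onset + int(np.argmin(s[onset : seg_start + 1]))
        end = seg_end + int(np.argmin(s[seg_end : end + 1]))
        prev_end = end
        if (end - onset) * dt < cfg.min_cycle_duration_s:
            continue
        t_onset = float(t[onset])
        t_end = float(t[end])
        # at-rest samples: top-amplitude region with |velocity| below eps
        top_level = base + cfg.top_region_fraction * amp_est
        rest = (s[onset : end + 1] >= top_level) & (np.abs(v[onset : end + 1]) <= eps)
        rest_idx = np.flatnonzero(rest) + onset
        if rest_idx.size == 0:
            # very short dwell: the velocity test can miss a plateau of a
            # few samples; fall back to the near-peak amplitude band
            near_peak = s[onset : end + 1] >= base + 0.97 * amp_est
            cand = np.flatnonzero(near_peak) + onset
            if cand.size >= 2:
                rest_idx = cand
        if rest_idx.size:
            b, r = int(rest_idx[0]), int(rest_idx[-1])
            plateau = float(np.median(x[b : r + 1]))
            # grid estimates as fallbacks for the flank fits
            t_bottom = (
                _interp_crossing(t[b - 1], t[b], v[b - 1], v[b], eps)
                if b > onset and abs(v[b - 1]) > eps else float(t[b])
            )
            t_rel_on = (
                _interp_crossing(t[r + 1], t[r], v[r + 1], v[r], eps)
                if r < end and abs(v[r + 1]) > eps else float(t[r])
            )
            rel_noise = sigma / amp_est
            band_lo = min(0.25, max(0.07, 4.0 * rel_noise))
            # fit windows tolerate a few samples of jitter in b/r: the
            # amplitude band masks out at-plateau samples anyway
            b_hi = min(b + 3, r)
            r_lo = max(r - 3, b)
            mid = (b + r) // 2
            for w0, w1 in ((onset, b_hi), (onset, mid)):
                fit = _flank_times(
                    t[w0 : w1 + 1], x[w0 : w1 + 1], s[w0 : w1 + 1],
                    base, plateau, band_lo, rel_noise, window_s,
                )
                if fit is not None:
                    f_on, f_bot = fit
                    if (t[onset] - 3 * dt <= f_on <= t[seg_start] + dt
                            and f_on < f_bot <= t[w1] + 2 * dt):
                        t_onset, t_bottom = f_on, f_bot
                        break
            for w0, w1 in ((r_lo, end), (mid, end)):
                fit = _flank_times(
                    t[w0 : w1 + 1], x[w0 : w1 + 1], s[w0 : w1 + 1],
                    base, plateau, band_lo, rel_noise, window_s,
                )
                if fit is not None:
                    f_end, f_rel = fit  # falling flank: y=pi at release onset
                    if (t[w0] - 2 * dt <= f_rel < f_end <= t[end] + 5 * dt
                            and f_end >= t[seg_end] - 5 * dt):
                        t_rel_on, t_end = f_rel, f_end
                        break
        else:
            # no dwell plateau (sharp peak): bottom = release onset = peak
            t_bottom = t_rel_on = float(t[peak_idx])
            plateau = float(s[peak_idx])
        if not (t_onset < t_bottom <= t_rel_on < t_end):
            t_bottom = t_rel_on = float(t[peak_idx])
            plateau = float(s[peak_idx])
            if not (t_onset < t_bottom <= t_rel_on < t_end):
                continue
        strikes.append(
            Strike(
                lever=lever,
                t_press_onset=t_onset,
                t_press_bottom=float(t_bottom),
                t_release_onset=float(t_rel_on),
                t_release_end=t_end,
                press_amplitude_mm=float(plateau - base),
                release_amplitude_mm=float(plateau - np.median(x[end : end + 3])),
            )
        )
    return strikes


def detect_strikes(trace: RaftTrace, config: DetectionConfig | None = None) -> List[Strike]:
    """Detect press/release cycles on both levers of a trace.

    Returns strikes merged across levers, ordered by press onset.  A
    trace with no supra-threshold activity (flat or too short) yields an
    empty list, not an error.
    """
    cfg = config or DetectionConfig()
    out: List[Strike] = []
    for lever in LEVERS:
        out.extend(
            _detect_lever(
                trace.time_s,
                trace.displacement_mm[lever],
                trace.sample_rate_hz,
                cfg,
                lever,
            )
        )
    out.sort(key=lambda s: s.t_press_onset)
    return out


@dataclass(frozen=True)
class AlternationReport:
    """Counts of departures from the instructed alternating pattern."""

    n_strikes: int
    n_same_lever_repeats: int
    n_overlapping_presses: int

    @property
    def n_violations(self) -> int:
        return self.n_same_lever_repeats + self.n_overlapping_presses


def alternation_report(strikes) -> AlternationReport:
    """Summarize alternation violations in an onset-ordered strike list.

    A same-lever repeat is two consecutive strikes on one lever; an
    overlapping press is a strike whose downstroke [press onset, press
    bottom) begins before the previous strike's downstroke has ended.
    (Full cycles legitimately overlap across levers in alternating
    tapping — one finger releases while the other presses — so only the
    downstrokes are compared.)  The input is not modified.
    """
    ordered = sorted(strikes, key=lambda s: s.t_press_onset)
    repeats = sum(
        1 for a, b in zip(ordered, ordered[1:]) if a.lever == b.lever
    )
    overlaps = sum(
        1 for a, b in zip(ordered, ordered[1:]) if b.t_press_onset < a.t_press_bottom
    )
    return AlternationReport(
        n_strikes=len(ordered),
        n_same_lever_repeats=repeats,
        n_overlapping_presses=overlaps,
    )
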