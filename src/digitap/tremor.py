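"""Per-strike tremor classification and tremor summary.

Tremor is flagged strike-by-strike, matching the scoring contract
downstream (tremor strikes are excluded from the Mobility metrics and
feed the Tremor Severity Score).  The classifier interface is
pluggable: any callable mapping (strikes, trace) to booleans can be
supplied, so a trained model can replace the default.  The built-in
default is a transparent kinematic heuristic — a stand-in, not a
reproduction of any published trained classifier: a strike is tremor
when its press amplitude falls well below the hand's typical amplitude
AND its local same-lever cycle rate lies in the classic rest-tremor
band (3-8 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .core import RaftTrace, Strike
from .errors import ClassifierError, ParameterError


@dataclass(frozen=True)
class TremorClassifierSpec:
    """Which per-strike tremor predictor to run.

    kind="heuristic" uses the built-in amplitude + cycle-rate rule;
    kind="external" delegates to ``predictor(strikes, trace)`` which
    must return one boolean per strike.
    """

    kind: str = "heuristic"
    amplitude_fraction_threshold: float = 0.45
    cycle_rate_band_hz: Tuple[float, float] = (3.0, 8.0)
    predictor: Optional[Callable] = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in ("heuristic", "external"):
            raise ParameterError(f"unknown classifier kind {self.kind!r}")
        if not 0 < self.amplitude_fraction_threshold < 1:
            raise ParameterError("amplitude_fraction_threshold must be in (0, 1)")
        lo, hi = self.cycle_rate_band_hz
        if not 0 < lo < hi:
            raise ParameterError("cycle_rate_band_hz must satisfy 0 < low < high")
        if self.kind == "external" and self.predictor is None:
            raise ParameterError("external classifier requires a predictor")


def _local_rates(onsets: np.ndarray) -> np.ndarray:
    """Local cycle rate per strike: reciprocal of the smaller onset gap
    to its same-lever neighbours (0 for an isolated strike)."""
    n = onsets.size
    rates = np.zeros(n)
    if n < 2:
        return rates
    gaps = np.diff(onsets)
    for i in range(n):
        cand = []
        if i > 0:
            cand.append(gaps[i - 1])
        if i < n - 1:
            cand.append(gaps[i])
        g = min(cand)
        rates[i] = 1.0 / g if g > 0 else np.inf
    return rates


def _heuristic_flags(strikes: Sequence[Strike], spec: TremorClassifierSpec) -> List[bool]:
    amps = np.array([s.press_amplitude_mm for s in strikes])
    med = float(np.median(amps))
    thresh = spec.amplitude_fraction_threshold * med
    lo, hi = spec.cycle_rate_band_hz
    flags = [False] * len(strikes)
    by_lever: dict = {}
    for i, s in enumerate(strikes):
        by_lever.setdefault(s.lever, []).append(i)
    for idx in by_lever.values():
        onsets = np.array([strikes[i].t_press_onset for i in idx])
        order = np.argsort(onsets)
        rates = np.empty_like(onsets)
        rates[order] = _local_rates(onsets[order])
        for j, i in enumerate(idx):
            flags[i] = bool(amps[i] < thresh and lo <= rates[j] <= hi)
    return flags


def classify_strikes(
    strikes: Sequence[Strike],
    trace: Optional[RaftTrace] = None,
    spec: Optional[TremorClassifierSpec] = None,
) -> List[Strike]:
    """Return a new strike list with ``is_tremor`` assigned.

    Deterministic given inputs; the input strikes are never mutated.
    An external predictor that raises or returns the wrong number of
    flags yields :class:`ClassifierError` and leaves the input intact.
    """
    spec = spec or TremorClassifierSpec()
    if not strikes:
        return []
    if spec.kind == "heuristic":
        flags = _heuristic_flags(strikes, spec)
    else:
        try:
            flags = list(spec.predictor(strikes, trace))
        except Exception as exc:  # noqa: BLE001 - wrap any predictor failure
            raise ClassifierError(f"external predictor failed: {exc}") from exc
        if len(flags) != len(strikes):
            raise ClassifierError(
                f"predictor returned {len(flags)} flags for {len(strikes)} strikes"
            )
    return [replace(s, is_tremor=bool(f)) for s, f in zip(strikes, flags)]


@dataclass
class TremorSummary:
    """Tremor inputs for severity scoring."""

    rest_tremor_pct: float
    tremor_amplitudes_mm: np.ndarray
    mean_tremor_amplitude_mm: Optional[float]


def tremor_summary(strikes: Sequence[Strike], trace_duration_s: float) -> TremorSummary:
    """Extract tremor percent-duration and tremor-strike amplitudes.

    Percent is the summed onset-to-release-end duration of flagged
    strikes over the trace duration; the mean amplitude is absent when
    nothing is flagged.
    """
    if trace_duration_s <= 0:
        raise ParameterError("trace duration must be positive")
    trem = [s for s in strikes if s.is_tremor]
    amps = np.array([s.press_amplitude_mm for s in trem])
    pct = 100.0 * sum(s.duration_s for s in trem) / trace_duration_s
    return TremorSummary(
        rest_tremor_pct=float(pct),
        tremor_amplitudes_mm=amps,
        mean_tremor_amplitude_mm=float(amps.mean()) if amps.size else None,
    )
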