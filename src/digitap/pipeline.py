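"""Trace-to-metrics composition used by the cohort simulator, the
session analyzer and the examples: detection -> tremor classification
-> per-finger metrics -> hand averaging.  Stateless; each stage can
equally be called on its own."""

from __future__ import annotations

from typing import List, Optional, Tuple

from .core import RaftTrace, Strike
from .detection import DetectionConfig, detect_strikes
from .metrics import HandMetrics, hand_metrics, per_finger_metrics, split_by_lever
from .tremor import TremorClassifierSpec, classify_strikes


def process_trace(
    trace: RaftTrace,
    detection_config: Optional[DetectionConfig] = None,
    classifier: Optional[TremorClassifierSpec] = None,
) -> Tuple[List[Strike], HandMetrics]:
    """Run the full kinematic pipeline on one trace."""
    strikes = detect_strikes(trace, detection_config)
    strikes = classify_strikes(strikes, trace, classifier)
    by_lever = split_by_lever(strikes)
    fm_index = per_finger_metrics(by_lever["index"], trace.duration_s)
    fm_middle = per_finger_metrics(by_lever["middle"], trace.duration_s)
    return strikes, hand_metrics(fm_index, fm_middle, strikes, trace.duration_s)


def extract_hand_metrics(
    trace: RaftTrace,
    detection_config: Optional[DetectionConfig] = None,
    classifier: Optional[TremorClassifierSpec] = None,
) -> HandMetrics:
    """Hand-level metrics of one trace (detection through averaging)."""
    return process_trace(trace, detection_config, classifier)[1]
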