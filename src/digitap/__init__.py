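"""digitap: kinematic analysis of repetitive alternating finger-tapping
(quantitative digitography) displacement traces.

Detects press/release cycles on two-lever tapping records, extracts the
validated kinematic metrics of the Parkinsonian motor signs
(bradykinesia, rigidity proxy, arrhythmicity, tremor), and scores them
against an age-adjusted healthy-control reference as a 0-100 Mobility
Score and a Tremor Severity Score.  A calibrated simulator generates
annotated synthetic traces so the whole pipeline is testable without
recorded data.
"""

from importlib import resources

from .core import (
    LEVERS,
    RaftTrace,
    ScoringConstants,
    Strike,
    TraceMeta,
    read_trace,
    write_strikes,
    write_trace,
)
from .detection import (
    AlternationReport,
    DetectionConfig,
    alternation_report,
    detect_strikes,
)
from .errors import (
    ClassifierError,
    DigitapError,
    InsufficientPerformanceError,
    ParameterError,
    ReferenceError_,
    ScoringError,
    TraceFormatError,
    TraceValidationError,
)
from .metrics import (
    FingerMetrics,
    HandMetrics,
    hand_metrics,
    per_finger_metrics,
    split_by_lever,
)
from .pipeline import extract_hand_metrics, process_trace
from .reporting import (
    ComplianceResult,
    MedicationEvent,
    SessionLog,
    SessionResult,
    TestRecord,
    analyze_session,
    compliance_ratio,
    timeseries_report,
)
from .scoring import (
    AGE_ADJUSTED_METRICS,
    MOBILITY_METRICS,
    MetricReference,
    NormativeReference,
    ScorePanel,
    age_adjust,
    build_reference,
    directional_z,
    fit_age_slope,
    flag_metric,
    mobility_score,
    score_panel,
    transform_press_amp_z,
    tremor_severity,
)
from .simulate import (
    CONTROL_AMPLITUDE_MEAN_MM,
    CONTROL_AMPLITUDE_SD_MM,
    SimulationParams,
    control_params,
    simulate_control_cohort,
    simulate_trace,
)
from .tremor import (
    TremorClassifierSpec,
    TremorSummary,
    classify_strikes,
    tremor_summary,
)

__version__ = "0.1.0"


def load_default_reference() -> NormativeReference:
    """Load the packaged normative reference.

    The packaged reference is *synthetic*: built from the calibrated
    control-cohort simulator (its press-amplitude distribution matches
    the published healthy-control calibration; all other distributions
    are simulator choices).  Use :func:`build_reference` with a real
    control table for clinical work.
    """
    with resources.as_file(
        resources.files("digitap") / "data" / "synthetic_reference.json"
    ) as p:
        return NormativeReference.from_json(p)
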