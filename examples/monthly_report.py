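"""Monthly compliance and medication-adherence reporting.

Builds a session log for a month of home testing, computes the
compliance ratio (distinct test days / possible test days) and the
16-of-30-days remote-monitoring criterion, and summarizes how far
actual dose times drifted from the prescribed schedule.
"""

import numpy as np

import digitap
from digitap import (
    MedicationEvent,
    SessionLog,
    TestRecord,
    analyze_session,
    compliance_ratio,
    simulate_trace,
    timeseries_report,
)
from digitap.simulate import control_params

rng = np.random.default_rng(5)
test_days = sorted(rng.choice(np.arange(1, 31), size=18, replace=False))
log = SessionLog(
    subject_id="S01",
    tests=[TestRecord(f"2024-04-{d:02d}T09:00:00+00:00", "R") for d in test_days],
    medications=[
        MedicationEvent(
            "carbidopa/levodopa", "25/100",
            prescribed_time=f"2024-04-{d:02d}T08:00:00+00:00",
            actual_time=(None if d % 7 == 0 else
                         f"2024-04-{d:02d}T08:{int(rng.integers(0, 45)):02d}:00+00:00"),
        )
        for d in range(1, 31, 3)
    ],
    more_affected_hand="R",
)

c = compliance_ratio([t.timestamp for t in log.tests], 2024, 4)
print(f"compliance: {c.days_tested}/{c.days_possible} days = {c.ratio:.3f}")
print(f"16-of-30-day monitoring criterion met: {c.monitoring_criterion_met}")

reference = digitap.load_default_reference()
analyzed = [
    (t.timestamp, t.hand,
     analyze_session(simulate_trace(control_params(60.0, rng), seed=i)[0], reference))
    for i, t in enumerate(log.tests)
]
doc = timeseries_report(log, analyzed, window_days=30)
deltas = [m["delta_minutes"] for m in doc["medication_adherence"]]
print(f"doses taken {len(deltas)}, missed {len(doc['missed_doses'])}; "
      f"mean dose delay {np.mean(deltas):.0f} min")
print(f"daily Mobility points: {len(doc['series']['R']['mobility_score'])}")
# A ratio >= 16/30 distinct days satisfies the remote-monitoring
# reimbursement requirement; dose deltas expose schedule drift.
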