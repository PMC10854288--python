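"""Regenerate the packaged synthetic normative reference.

Builds the reference from a 100-subject simulated healthy-control
cohort (trace-based: every trace goes through the full detection ->
classification -> metrics pipeline) and writes it to
src/digitap/data/synthetic_reference.json.  The cohort seed is fixed so
the packaged file is reproducible.
"""

from pathlib import Path

from digitap.scoring import build_reference
from digitap.simulate import simulate_control_cohort

COHORT_N = 100
COHORT_SEED = 20240

if __name__ == "__main__":
    table = simulate_control_cohort(COHORT_N, seed=COHORT_SEED)
    ref = build_reference(table, synthetic=True)
    out = Path(__file__).resolve().parents[1] / "src" / "digitap" / "data" / "synthetic_reference.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    ref.to_json(out)
    print(f"wrote {out} (n={ref.n_subjects})")
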