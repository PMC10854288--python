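import numpy as np
import pytest

import digitap
from digitap.core import RaftTrace, TraceMeta
from digitap.simulate import SimulationParams, simulate_trace


@pytest.fixture(scope="session")
def reference():
    """Packaged synthetic normative reference."""
    return digitap.load_default_reference()


@pytest.fixture(scope="session")
def clean_trace_and_truth():
    """Noise-free, jitter-free control-like trace with ground truth."""
    params = SimulationParams(noise_sd_mm=0.0, isi_cv=0.0)
    return simulate_trace(params, seed=1)


@pytest.fixture()
def flat_trace():
    n = 3000
    return RaftTrace(
        sample_rate_hz=100.0,
        time_s=np.arange(n) / 100.0,
        displacement_mm={"index": np.zeros(n), "middle": np.zeros(n)},
        meta=TraceMeta(subject_id="FLAT"),
    )


def pair_strikes(truth, detected):
    """Sort both strike lists per (lever, onset) for positional matching;
    fails the calling test if counts differ."""
    assert len(truth) == len(detected), "strike count mismatch"
    key = lambda s: (s.lever, s.t_press_onset)  # noqa: E731
    return list(zip(sorted(truth, key=key), sorted(detected, key=key)))
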