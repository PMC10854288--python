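# Methods

`digitap` quantifies the motor signs of Parkinson's disease from a
30-second repetitive alternating finger-tapping (RAFT) test performed
on two adjacent instrumented levers (quantitative digitography). The
input is a pair of displacement time series (mm, fixed sampling rate,
default 100 Hz), one per lever ("index" and "middle"). The pipeline
has four stages — strike detection, per-strike tremor classification,
kinematic metric extraction, and normative scoring — plus a synthetic
trace generator used for validation and for the packaged reference.

## Strike detection

Each lever is processed independently. The signal is smoothed with a
centered moving average (default window 0.02 s, rounded to an odd
sample count) and press segments are found by hysteresis thresholding
(pressed at ≥ 0.3 mm, released at ≤ 0.15 mm; both scale with the
signal if the device gain changes, and `DetectionConfig.scaled` keeps
detection equivariant under amplitude rescaling). Segments still open
at either trace boundary are dropped: partial cycles bias every
duration metric. A cycle shorter than `min_cycle_duration_s`
(default 0.05 s) is discarded.

Within a segment, four phase times are estimated:

* **press onset** — start of downward lever motion;
* **press bottom** — arrival at rest at the bottom of the press;
* **release onset** — departure from rest;
* **release end** — return to baseline.

The rest interval (dwell) is located as the samples in the
top-amplitude region (≥ 85 % of segment amplitude) whose smoothed
velocity magnitude is below `bottom_velocity_epsilon_mm_s` (default
2 mm/s); when a short dwell leaves no such sample, the near-peak
amplitude band (≥ 97 %) is used instead, and a segment with neither
(a sharp triangular peak) gets bottom = release onset = the peak, i.e.
zero dwell.

Grid-resolution estimates of the boundaries are then refined below the
sample grid with a *flank model*: a smooth ballistic stroke between two
rest levels is well described by a raised-cosine displacement flank
(equivalently a cosine-bell velocity profile, the standard smooth-stroke
shape), for which `arccos(1 − 2·(x − base)/amplitude)` is exactly
linear in time. A variance-weighted least-squares line through the
mid-flank samples (fractional-amplitude band, default 7–93 %, widened
when the noise estimate is large) yields both boundary times of the
flank — where the line reaches 0 and π. At relative noise above ~1 %
the fit runs on the smoothed signal and the known boxcar attenuation of
the cosine component (a sinc factor in the flank duration) is inverted
analytically in a second pass. Every fit is validated against the
grid-level estimates and windows; on failure the detector falls back to
the interpolated velocity-epsilon crossing, and finally to the grid
sample itself.

Accuracy, measured against the simulator's ground truth: on noise-free
traces all four phase times are exact to well below one sample and
amplitudes to < 0.01 mm; at 0.02 mm sensor noise phase errors are
≈ 0.1 sample; at 0.1 mm noise the 95th percentile of phase errors stays
within 2 samples across the amplitude (2–9 mm) × rate (1–4 Hz per
finger) grid, with rare single-strike outliers up to ~5 samples.
Strike *counts* are recovered exactly (100 % recall and precision)
throughout that grid. The baseline of each press is the median of the
below-threshold samples in the preceding half second; the plateau level
is the median of the rest-interval samples, making the press amplitude
robust to a few mis-assigned boundary samples.

## Tremor classification

Tremor is flagged per strike, matching the downstream scoring contract
(tremor strikes are excluded from all Mobility metrics and feed the
Tremor Severity Score). The classifier is pluggable: any callable
mapping (strikes, trace) to booleans can be supplied through
`TremorClassifierSpec(kind="external", predictor=...)`, so a trained
model can be dropped in. The built-in default is a transparent
kinematic heuristic — a stand-in, not a reproduction of any trained
classifier: a strike is tremor when its press amplitude is below 45 %
of the hand's median strike amplitude *and* its local same-lever cycle
rate (reciprocal of the smaller onset gap to its same-lever
neighbours) lies in the 3–8 Hz rest-tremor band. Because the
amplitude criterion is relative, uniformly small (severely
bradykinetic) tapping is not misread as tremor; because the rate
criterion is local, isolated small strikes are not flagged either.
The default does not distinguish rest from action tremor; all flagged
strikes contribute to the rest-tremor percentage.

## Kinematic metrics

Eight metrics are computed per finger over voluntary strikes only and
averaged, unweighted, across the two fingers: press amplitude (mm) and
its coefficient of variation (a proxy for the sequence effect), the
inter-strike interval ISI (s; onset-to-onset of one finger, the time to
complete one cycle of that finger's movement) and its CV
("arrhythmicity", reported ×100 in percent), press speed and release
slope (amplitude/duration, mm/s; release slope is the rigidity proxy
and is the same quantity the dashboard calls "release speed"), dwell
time (s), and rest tremor % (summed tremor-strike durations over the
trace duration). Taps/min counts voluntary strikes of both fingers.
CVs use the sample (n−1) standard deviation. A finger with fewer than
two voluntary strikes yields an all-absent record; absence propagates
through hand averaging, and a session in that state is reported as
"insufficient performance" with no scores (the redo-the-test case).

One robustness rule: ISI intervals longer than 2.5× the finger's
median interval are excluded from the ISI mean/CV. An interval that
spans a pause — most commonly a tremor episode during which voluntary
tapping stops — is not a movement cycle, and without the rule a trace
with 18 % tremor but otherwise normal tapping would score Mobility ≈ 0
from an exploded ISI CV. Dwell time is computed and reported but never
scored: it is not one of the six Mobility metrics.

## Normative reference and scoring

`build_reference` takes a control table (one row per session:
`subject_id`, `age_years`, the seven kinematic metrics). Age slopes
are estimated for the three metrics with a known age effect — press
amplitude CV, release slope, press speed — by a linear mixed-effects
model with a fixed effect of age and a random intercept per subject
(REML, via statsmodels `MixedLM`); with one observation per subject
this reduces to ordinary least squares, which is then used directly
(and is the fallback if the mixed fit fails). Control values of those
metrics are adjusted to the reference age of 60 years by
`value − slope·(age − 60)` — mapping every subject to their expected
value at 60, the direction that makes controls of all ages share one
distribution. Means, sample SDs, and the abnormality thresholds are
taken over the adjusted values; thresholds sit at the 25th percentile
for lower-is-worse metrics (press amplitude, press speed, release
slope, taps/min, Mobility Score) and the 75th for higher-is-worse ones
(ISI, ISI CV, press amplitude CV), with percentiles computed by linear
interpolation between order statistics. Values equal to a threshold
are normal. The control Mobility Score distribution is computed
against the freshly built reference so the score itself can be
thresholded like any metric.

An incoming session is scored as:

* directional z per metric: `z = (adjusted − mean)/SD`, sign-flipped
  where lower is worse, floored at 0 so above-average performance never
  offsets a deficit;
* press-amplitude z transform: identity for z ≤ 10, `3.2·z^0.495`
  above, clamped at 20. The control amplitude distribution is so tight
  (8.67 ± 0.12 mm) that |z| = 10 corresponds to only 7.5 mm; without
  the compression a single metric would dominate the composite. The
  constants make the transition continuous (3.2·10^0.495 = 10.004) and
  the clamp enforces the stated bound of 20, which the bare power law
  would exceed for z ≳ 40;
* **Mobility Score** = `100 − 14 × mean(z)` over the six metrics
  {ISI, ISI CV, press speed, press amplitude, press amplitude CV,
  release slope}, clamped to [0, 100]. 100 means control-mean
  performance in every metric; the floor at 0 is an explicit clamp
  (the formula itself can go negative);
* **Tremor Severity** = `%RT + 100 × mean((Amp_i/AmpMax)²)` over
  tremor strikes, where `AmpMax` is the maximum possible lever
  displacement. When %RT < 10 the amplitude component is suppressed by
  `RTamp = 4^(0.05·%RT − 1)` — by default as a multiplicative factor
  (0.25 at 0 %, 0.5 just below 10 %); a "replace" mode (the component
  becomes `100·RTamp²`) and an "off" mode are selectable, since how
  RTamp combines with the amplitude term is genuinely open. The
  default introduces a factor-two step at exactly 10 %, which is
  documented rather than smoothed. The score has no upper cap and no
  tremor strikes means the score equals %RT alone.

`AmpMax` is not published for the device; the default 12.5 mm is
back-computed from a printed worked example (severity 41 at 18 %
tremor with 5.7 mm mean tremor amplitude) and is configurable in
`ScoringConstants`. The printed worked severity values cannot be
reconciled exactly with the formula without the per-strike data, so
they constrain but do not pin this constant.

## Synthetic traces and the packaged reference

The generator renders each strike as a raised-cosine downstroke, flat
dwell, raised-cosine upstroke; per-finger onsets follow a log-normal
renewal process with configurable mean ISI and CV; amplitudes decay
multiplicatively per tap (sequence effect) with optional per-tap
log-jitter; tremor is modelled as bursts (≤ 5 strikes) of
low-amplitude strikes at `tremor_rate_hz` (default 5 Hz) on a single
lever per burst — matching the per-strike classification contract —
sized so the summed strike durations hit the requested percentage of
the trace; voluntary strikes colliding with a burst window are
displaced. Gaussian sensor noise (default SD 0.02 mm, a choice
consistent with a precision-engineered lever sensor; never stated for
the device) is added and clipped at zero displacement. Output is
bit-reproducible per (params, seed).

The control-cohort generator draws per-subject parameters so that the
*pipeline-extracted* session-mean press amplitude is distributed as
the published healthy-control calibration, 8.67 ± 0.12 mm (the
first-tap amplitude is inflated by the expected decay factor of the
session). All other control distributions are synthetic choices made
once for clinical plausibility: ISI 0.5 s ± 8 % between subjects with
5 % within-session CV, press/release ≈ 0.12 s slowing by ~0.4–0.5 %
per year past 60, dwell 0.08 s, and a mild age trend in amplitude
variability — giving the reference-builder genuine age effects to
absorb. A `trace_based=False` mode draws metric rows directly from
matching distributions for large-n distributional checks where
rendering 10,000 traces would add nothing.

What passing tests on this generator do **not** show: the raised-cosine
flank assumption is exactly true of the simulator, so the sub-sample
phase accuracy reported above is an upper bound for real strokes with
asymmetric or irregular flanks (the fallback estimators bound the
degradation at roughly one or two samples); the tremor heuristic's
near-perfect F1 reflects the simulator's clean amplitude/rate
separation, not expected performance on real tremor, which is why the
classifier is pluggable; and no claim is made about clinical
associations (e.g. with MDS-UPDRS III), which require patient cohorts.

The packaged reference (`digitap/data/synthetic_reference.json`,
loaded by `load_default_reference()`) is built from 100 simulated
control subjects, trace-based, fixed seed
(`scripts/make_default_reference.py` regenerates it). It is clearly
labelled synthetic in the file and in the API; clinical use requires a
reference built from real control data.

## Compliance and reporting

The monthly compliance ratio is distinct calendar days with ≥ 1
completed test divided by the possible test days — the full month once
it has passed, otherwise the days elapsed through "today" (a choice;
the source is silent on in-progress months). Tests are counted per
subject-day regardless of hand. The remote-monitoring criterion is
met when any 30-day window contains at least 16 distinct test days.
Medication adherence is reported as actual − prescribed dose time in
minutes, with missed doses (no actual time) listed separately.
Timestamps are ISO-8601 and must be timezone-aware. All reports are
pure functions of their inputs; JSON schemas carry a version field.

## Numerical choices and degenerate inputs

Trace files are long-format TSV with a JSON header, written at six
decimal places (the declared precision; round-tripping is exact at
that precision). Validation is total: malformed input raises a typed
error, never a partial object. Time spacing must match the declared
rate within 1 µs; displacement must be non-negative and, when a device
maximum is supplied, within it. A constant control column is a build
error (zero SD); SDs below 10⁻¹⁰ relative are treated as zero. A
cohort at a single age skips age-slope fitting (identity adjustment);
fewer than 10 control subjects triggers a warning, fewer than 2 an
error. Ties at detection thresholds resolve to the earliest sample.

## Problem sizes used in the test suite

The suite simulates 30 s traces at 100 Hz (≈ 120 strikes), a
42-subject trace-based cohort for the calibration checks, and a
10,000-row parametric cohort for the quartile-flag rate; the full run
completes in well under a minute. These sizes were chosen to exercise
every code path at the study's native scale.
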