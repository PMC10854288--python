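"""Normative reference building and severity scoring.

The healthy-control reference stores, per metric, an age-adjusted
control mean and SD, the worse-performance direction, and an abnormal
threshold at the 25th (lower-is-worse) or 75th (higher-is-worse)
percentile of the control distribution.  Incoming values are adjusted
to a reference age of 60 years (for the three metrics with a
significant age effect: press amplitude CV, release slope, press
speed), converted to directional z-scores — sign flipped where lower
is worse, floored at 0 so above-average performance never inflates a
score — and combined:

    Mobility = 100 - 14 * mean(z_i)  over the six metrics
               {ISI, ISI CV, press speed, press amplitude,
                press amplitude CV, release speed},  clamped to [0, 100]

with the press-amplitude z passed through a saturating power law
(A * z^k, A = 3.2, k = 0.495, capped at 20) above z = 10, because the
extremely tight control amplitude distribution (8.67 +/- 0.12 mm)
would otherwise let a single metric dominate.

    Tremor Severity = %RT + 100 * mean((Amp_i / AmpMax)^2)

over tremor strikes, with the amplitude term suppressed by the factor
4^(0.05 * %RT - 1) when %RT < 10.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ScoringConstants
from .errors import ParameterError, ReferenceError_, ScoringError
from .metrics import HandMetrics

REFERENCE_SCHEMA_VERSION = 1

#: metrics entering the Mobility Score (directional z averaged over these)
MOBILITY_METRICS = (
    "isi_s",
    "isi_cv",
    "press_speed_mm_s",
    "press_amplitude_mm",
    "press_amplitude_cv",
    "release_slope_mm_s",
)

#: metrics whose control distribution has a significant age effect
AGE_ADJUSTED_METRICS = ("press_amplitude_cv", "release_slope_mm_s", "press_speed_mm_s")

LOWER_WORSE = frozenset(
    {"press_amplitude_mm", "press_speed_mm_s", "release_slope_mm_s",
     "taps_per_minute", "mobility_score"}
)
HIGHER_WORSE = frozenset({"isi_s", "isi_cv", "press_amplitude_cv"})

#: every metric carried by a reference
REFERENCE_METRICS = tuple(sorted(LOWER_WORSE | HIGHER_WORSE))


@dataclass
class AgeSlopeFit:
    """Fixed-effect age slope (units of the metric per year)."""

    slope: float
    stderr: float
    method: str  # "mixedlm" or "ols"


def fit_age_slope(values, ages, subject_ids) -> AgeSlopeFit:
    """Fit the age effect on a metric with a random-intercept model.

    A linear mixed-effects model with a fixed effect of age and a
    random intercept per subject (REML).  With one observation per
    subject the model reduces to ordinary least squares, which is then
    used directly; OLS is also the fallback if the mixed fit fails to
    converge.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if values.size != ages.size or values.size != subject_ids.size:
        raise ParameterError("values, ages and subject_ids must be equal length")
    if np.unique(ages).size < 2:
        raise ParameterError("degenerate design: age is constant")
    exog = sm.add_constant(ages)
    _, counts = np.unique(subject_ids, return_counts=True)
    if counts.max() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(values, exog, groups=subject_ids).fit(reml=True)
            return AgeSlopeFit(float(fit.params[1]), float(fit.bse[1]), "mixedlm")
        except Exception:  # singular / non-converged: fall back to OLS
            pass
    fit = sm.OLS(values, exog).fit()
    return AgeSlopeFit(float(fit.params[1]), float(fit.bse[1]), "ols")


def age_adjust(
    value: float,
    age_years: float,
    slope: Optional[float],
    reference_age_years: float = 60.0,
) -> float:
    """Map a value to its expected equivalent at the reference age.

    adjusted = value - slope * (age - reference_age); a ``None`` slope
    is the identity (metric not age-adjusted).
    """
    if age_years < 0:
        raise ParameterError(f"negative age: {age_years}")
    if slope is None:
        return value
    return value - slope * (age_years - reference_age_years)


@dataclass
class MetricReference:
    """Control distribution summary for one metric."""

    mean: float
    sd: float
    direction: str  # "lower_worse" | "higher_worse"
    threshold: float
    threshold_side: str  # "lower" | "upper"
    age_slope: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "direction": self.direction,
            "threshold": self.threshold, "threshold_side": self.threshold_side,
            "age_slope": self.age_slope,
        }


@dataclass
class NormativeReference:
    """Healthy-control reference for scoring and flagging."""

    metrics: Dict[str, MetricReference]
    constants: ScoringConstants = field(default_factory=ScoringConstants)
    n_subjects: int = 0
    synthetic: bool = False
    schema_version: int = REFERENCE_SCHEMA_VERSION

    def __getitem__(self, metric: str) -> MetricReference:
        try:
            return self.metrics[metric]
        except KeyError:
            raise ReferenceError_(f"unknown metric {metric!r}") from None

    def adjust(self, metric: str, value: float, age_years: Optional[float]) -> float:
        """Age-adjust ``value`` for ``metric`` (identity when the metric
        has no age slope or the age is unknown)."""
        entry = self[metric]
        if age_years is None:
            return value
        return age_adjust(
            value, age_years, entry.age_slope, self.constants.reference_age_years
        )

    def to_json(self, path) -> None:
        doc = {
            "schema_version": self.schema_version,
            "kind": "digitap-normative-reference",
            "synthetic": self.synthetic,
            "n_subjects": self.n_subjects,
            "constants": self.constants.to_dict(),
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "NormativeReference":
        doc = json.loads(Path(path).read_text())
        if doc.get("kind") != "digitap-normative-reference":
            raise ReferenceError_(f"{path} is not a reference file")
        if doc.get("schema_version") != REFERENCE_SCHEMA_VERSION:
            raise ReferenceError_(
                f"unsupported reference schema {doc.get('schema_version')}"
            )
        return cls(
            metrics={k: MetricReference(**v) for k, v in doc["metrics"].items()},
            constants=ScoringConstants.from_dict(doc["constants"]),
            n_subjects=int(doc.get("n_subjects", 0)),
            synthetic=bool(doc.get("synthetic", False)),
        )


def directional_z(value: float, mean: float, sd: float, direction: str) -> float:
    """Severity z-score: raw z, sign-flipped where lower is worse, then
    floored at 0 (above-average performance does not offset deficits)."""
    if sd <= 0:
        raise ReferenceError_(f"non-positive reference SD: {sd}")
    if direction not in ("lower_worse", "higher_worse"):
        raise ReferenceError_(f"unknown direction {direction!r}")
    z = (value - mean) / sd
    if direction == "lower_worse":
        z = -z
    return max(0.0, z)


def transform_press_amp_z(z: float, constants: Optional[ScoringConstants] = None) -> float:
    """Saturating power-law compression of the press-amplitude z.

    Identity on [0, 10]; A * z^k (A = 3.2, k = 0.495) above, capped at
    20.  A * 10^k = 10.004, so the transition at z = 10 is continuous
    to within printed precision.
    """
    c = constants or ScoringConstants()
    if z < 0:
        raise ParameterError("directional z must be >= 0")
    if z <= c.pa_z_transition:
        return float(z)
    return float(min(c.pa_transform_A * z ** c.pa_transform_k, c.pa_z_cap))


def mobility_score(
    z_by_metric: Dict[str, float], constants: Optional[ScoringConstants] = None
) -> float:
    """Mobility Score from the six directional z-scores.

    ``z_by_metric`` must contain every metric in
    :data:`MOBILITY_METRICS`, with the press-amplitude z already
    transformed.  100 = performance at the control mean in every
    metric; clamped to [0, 100].
    """
    c = constants or ScoringConstants()
    zs = []
    for m in MOBILITY_METRICS:
        z = z_by_metric.get(m)
        if z is None:
            raise ScoringError(f"missing directional z for metric {m!r}")
        if z < 0:
            raise ScoringError(f"directional z for {m!r} is negative")
        zs.append(z)
    score = 100.0 - c.mobility_scale * float(np.mean(zs))
    return float(min(100.0, max(0.0, score)))


def tremor_severity(
    rest_tremor_pct: float,
    tremor_amplitudes_mm: Sequence[float],
    constants: Optional[ScoringConstants] = None,
    suppression_mode: str = "scale",
) -> float:
    """Tremor Severity Score.

    pct + 100 * mean((Amp_i / AmpMax)^2) over tremor strikes.  Below
    10% tremor the amplitude component is suppressed using
    RTamp = 4^(0.05 * pct - 1) — by default as a multiplicative factor
    on the component (``suppression_mode="scale"``); mode ``"replace"``
    substitutes 100 * RTamp^2 for the component, ``"off"`` disables
    suppression.  No upper cap (the formula permits scores above 100).
    """
    c = constants or ScoringConstants()
    if not 0.0 <= rest_tremor_pct <= 100.0:
        raise ParameterError("rest_tremor_pct must be in [0, 100]")
    if suppression_mode not in ("scale", "replace", "off"):
        raise ParameterError(f"unknown suppression_mode {suppression_mode!r}")
    amps = np.asarray(tremor_amplitudes_mm, dtype=float)
    if amps.size == 0:
        return float(rest_tremor_pct)
    if np.any(amps < 0) or np.any(amps > c.amp_max_mm):
        raise ParameterError("tremor amplitudes must lie in [0, amp_max_mm]")
    component = 100.0 * float(np.mean((amps / c.amp_max_mm) ** 2))
    if rest_tremor_pct < c.low_tremor_pct_threshold and suppression_mode != "off":
        rt_amp = c.rt_A ** (c.rt_k * rest_tremor_pct + c.rt_b)
        if suppression_mode == "scale":
            component *= rt_amp
        else:  # replace
            component = 100.0 * rt_amp**2
    return float(rest_tremor_pct + component)


def flag_metric(value: float, entry: MetricReference) -> str:
    """"normal" or "abnormal" against the percentile threshold.

    Lower-is-worse metrics are abnormal strictly below the 25th control
    percentile; higher-is-worse strictly above the 75th.  Values equal
    to the threshold are normal.
    """
    if entry.threshold_side == "lower":
        return "abnormal" if value < entry.threshold else "normal"
    return "abnormal" if value > entry.threshold else "normal"


# ---------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------

_TABLE_METRICS = tuple(m for m in REFERENCE_METRICS if m != "mobility_score")


def build_reference(
    control_table: pd.DataFrame,
    constants: Optional[ScoringConstants] = None,
    synthetic: bool = False,
) -> NormativeReference:
    """Build a :class:`NormativeReference` from a control metric table.

    The table needs one row per control session with columns
    ``subject_id``, ``age_years`` and the seven kinematic metrics.  Age
    slopes are fitted (random-intercept model) for the three
    age-affected metrics when ages vary, every control value of those
    metrics is adjusted to the reference age, and means, sample SDs and
    the 25th/75th percentile thresholds are taken over the adjusted
    values (percentiles by linear interpolation between order
    statistics).  The control Mobility Score distribution is then
    computed against the freshly built reference so the score itself
    can be thresholded and flagged like any metric.
    """
    c = constants or ScoringConstants()
    required = {"subject_id", "age_years", *_TABLE_METRICS}
    missing = required - set(control_table.columns)
    if missing:
        raise ReferenceError_(f"control table missing columns {sorted(missing)}")
    n_subjects = control_table["subject_id"].nunique()
    if n_subjects < 2:
        raise ReferenceError_("need at least 2 control subjects")
    if n_subjects < 10:
        warnings.warn(
            f"only {n_subjects} control subjects; reference percentiles will be "
            "unstable (>= 10 recommended)",
            stacklevel=2,
        )
    ages = control_table["age_years"].to_numpy(dtype=float)
    varying_age = np.unique(ages).size >= 2

    slopes: Dict[str, Optional[float]] = {}
    adjusted = {}
    for m in _TABLE_METRICS:
        col = control_table[m].to_numpy(dtype=float)
        if m in AGE_ADJUSTED_METRICS and varying_age:
            fit = fit_age_slope(col, ages, control_table["subject_id"].to_numpy())
            slopes[m] = fit.slope
            adjusted[m] = col - fit.slope * (ages - c.reference_age_years)
        else:
            slopes[m] = None
            adjusted[m] = col

    metrics: Dict[str, MetricReference] = {}
    for m in _TABLE_METRICS:
        vals = adjusted[m]
        sd = float(np.std(vals, ddof=1))
        if sd <= 1e-10 * max(1.0, abs(float(np.mean(vals)))) or not np.isfinite(sd):
            raise ReferenceError_(f"constant control column {m!r} (zero SD)")
        if m in LOWER_WORSE:
            direction, side, q = "lower_worse", "lower", 25.0
        else:
            direction, side, q = "higher_worse", "upper", 75.0
        metrics[m] = MetricReference(
            mean=float(np.mean(vals)),
            sd=sd,
            direction=direction,
            threshold=float(np.percentile(vals, q)),
            threshold_side=side,
            age_slope=slopes[m],
        )

    # control Mobility Score distribution (rows are already adjusted)
    control_scores = []
    for i in range(len(control_table)):
        zmap = {}
        for m in MOBILITY_METRICS:
            z = directional_z(
                float(adjusted[m][i]), metrics[m].mean, metrics[m].sd,
                metrics[m].direction,
            )
            if m == "press_amplitude_mm":
                z = transform_press_amp_z(z, c)
            zmap[m] = z
        control_scores.append(mobility_score(zmap, c))
    scores = np.asarray(control_scores)
    score_sd = float(np.std(scores, ddof=1))
    metrics["mobility_score"] = MetricReference(
        mean=float(scores.mean()),
        sd=score_sd if score_sd > 0 else 1.0,
        direction="lower_worse",
        threshold=float(np.percentile(scores, 25.0)),
        threshold_side="lower",
        age_slope=None,
    )
    return NormativeReference(
        metrics=metrics, constants=c, n_subjects=int(n_subjects), synthetic=synthetic
    )


# ---------------------------------------------------------------------
# Score panel
# ---------------------------------------------------------------------

@dataclass
class MetricScore:
    """One metric's scoring breakdown."""

    raw: float
    adjusted: float
    raw_z: float
    directional_z: float
    transformed_z: Optional[float]  # press amplitude only
    flag: str  # "normal" | "abnormal"


@dataclass
class ScorePanel:
    """Scores and per-metric breakdown for one analyzed hand/session."""

    mobility_score: float
    tremor_severity: float
    metrics: Dict[str, MetricScore]
    mobility_flag: str
    rest_tremor_pct: float
    mean_tremor_amplitude_mm: Optional[float]

    def to_dict(self) -> dict:
        return {
            "mobility_score": self.mobility_score,
            "mobility_flag": self.mobility_flag,
            "tremor_severity": self.tremor_severity,
            "rest_tremor_pct": self.rest_tremor_pct,
            "mean_tremor_amplitude_mm": self.mean_tremor_amplitude_mm,
            "metrics": {
                k: {
                    "raw": v.raw, "adjusted": v.adjusted, "raw_z": v.raw_z,
                    "directional_z": v.directional_z,
                    "transformed_z": v.transformed_z, "flag": v.flag,
                }
                for k, v in self.metrics.items()
            },
        }


def score_panel(
    hand: HandMetrics,
    reference: NormativeReference,
    age_years: Optional[float] = None,
    tremor_amplitudes_mm: Optional[Sequence[float]] = None,
    suppression_mode: str = "scale",
) -> ScorePanel:
    """Score one hand-metric record against a normative reference.

    Computes, per metric: age-adjusted value, raw and directional z,
    the press-amplitude transform, and the normal/abnormal flag; then
    the Mobility Score over the six scored metrics and the Tremor
    Severity Score from the tremor summary.  ``tremor_amplitudes_mm``
    are the press amplitudes of the tremor strikes (empty/None = no
    tremor strikes).
    """
    if not hand.complete:
        raise ScoringError("hand metrics incomplete; cannot score")
    c = reference.constants
    raw_values = hand.to_dict()
    panel_metrics: Dict[str, MetricScore] = {}
    zmap: Dict[str, float] = {}
    for m in _TABLE_METRICS:
        entry = reference[m]
        raw = float(raw_values[m])
        adj = reference.adjust(m, raw, age_years)
        raw_z = (adj - entry.mean) / entry.sd
        dz = directional_z(adj, entry.mean, entry.sd, entry.direction)
        tz = None
        if m == "press_amplitude_mm":
            tz = transform_press_amp_z(dz, c)
            zmap[m] = tz
        elif m in MOBILITY_METRICS:
            zmap[m] = dz
        panel_metrics[m] = MetricScore(
            raw=raw, adjusted=adj, raw_z=float(raw_z), directional_z=float(dz),
            transformed_z=tz, flag=flag_metric(adj, entry),
        )
    mob = mobility_score(zmap, c)
    amps = tremor_amplitudes_mm if tremor_amplitudes_mm is not None else []
    sev = tremor_severity(hand.rest_tremor_pct, amps, c, suppression_mode)
    amps_arr = np.asarray(amps, dtype=float)
    return ScorePanel(
        mobility_score=mob,
        tremor_severity=sev,
        metrics=panel_metrics,
        mobility_flag=flag_metric(mob, reference["mobility_score"]),
        rest_tremor_pct=hand.rest_tremor_pct,
        mean_tremor_amplitude_mm=float(amps_arr.mean()) if amps_arr.size else None,
    )
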