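"""Normative reference, z-scores, Mobility and Tremor Severity Scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digitap.core import ScoringConstants
from digitap.errors import ParameterError, ReferenceError_, ScoringError
from digitap.metrics import HandMetrics
from digitap.scoring import (
    MOBILITY_METRICS,
    MetricReference,
    NormativeReference,
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
from digitap.simulate import simulate_control_cohort

C = ScoringConstants()


class TestAgeSlope:
    def test_noiseless_linear_data_reduces_to_ols(self):
        ages = np.linspace(40, 80, 20)
        values = 1.0 + 0.01 * ages
        fit = fit_age_slope(values, ages, [f"s{i}" for i in range(20)])
        assert fit.method == "ols"
        assert fit.slope == pytest.approx(0.01, abs=1e-10)

    def test_age_independent_values_give_null_slope(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(40, 80, 60)
        values = rng.normal(5.0, 0.3, 60)
        fit = fit_age_slope(values, ages, [f"s{i}" for i in range(60)])
        assert abs(fit.slope) < 2 * fit.stderr

    @staticmethod
    def _random_intercept_fit(seed):
        """Slope 0.02/yr, intercept SD 1, noise SD 0.5, 40 subjects x 2."""
        rng = np.random.default_rng(seed)
        n_subj = 40
        ages = rng.uniform(40, 80, n_subj)
        intercepts = rng.normal(0.0, 1.0, n_subj)
        rows, row_ages, row_ids = [], [], []
        for i in range(n_subj):
            for _ in range(2):
                rows.append(10 + 0.02 * ages[i] + intercepts[i] + rng.normal(0, 0.5))
                row_ages.append(ages[i])
                row_ids.append(f"s{i}")
        return fit_age_slope(rows, row_ages, row_ids)

    def test_random_intercept_model_recovers_slope(self):
        fit = self._random_intercept_fit(2)
        assert fit.method == "mixedlm"
        assert fit.slope == pytest.approx(0.02, rel=0.25)

    def test_constant_age_is_degenerate(self):
        with pytest.raises(ParameterError, match="degenerate"):
            fit_age_slope([1.0, 2.0], [60.0, 60.0], ["a", "b"])


class TestAgeAdjust:
    def test_reference_age_is_identity(self):
        assert age_adjust(1.23, 60.0, 0.05) == pytest.approx(1.23)

    def test_zero_or_absent_slope_is_identity(self):
        assert age_adjust(1.23, 75.0, 0.0) == pytest.approx(1.23)
        assert age_adjust(1.23, 75.0, None) == pytest.approx(1.23)

    def test_subtracts_expected_age_effect(self):
        # value 1.00 at age 70 with slope 0.01/yr maps to 0.90 at 60
        assert age_adjust(1.00, 70.0, 0.01) == pytest.approx(0.90)

    def test_negative_age_rejected(self):
        with pytest.raises(ParameterError):
            age_adjust(1.0, -5.0, 0.01)


class TestDirectionalZ:
    def test_value_at_mean_is_zero(self):
        assert directional_z(8.67, 8.67, 0.12, "lower_worse") == 0.0

    def test_low_amplitude_flips_to_positive(self):
        # 8.43 vs mean 8.67, SD 0.12: raw z -2 -> directional +2
        assert directional_z(8.43, 8.67, 0.12, "lower_worse") == pytest.approx(2.0)

    def test_above_mean_isi_is_unflipped(self):
        assert directional_z(0.6, 0.5, 0.1, "higher_worse") == pytest.approx(1.0)

    def test_above_average_performance_floors_at_zero(self):
        assert directional_z(9.0, 8.67, 0.12, "lower_worse") == 0.0
        assert directional_z(0.4, 0.5, 0.1, "higher_worse") == 0.0

    def test_non_positive_sd_rejected(self):
        with pytest.raises(ReferenceError_):
            directional_z(1.0, 1.0, 0.0, "lower_worse")


class TestPressAmpTransform:
    def test_identity_below_transition(self):
        assert transform_press_amp_z(5.0, C) == 5.0

    def test_continuous_at_transition(self):
        # A * 10^k = 10 within 0.05
        assert transform_press_amp_z(10.0 + 1e-12, C) == pytest.approx(10.0, abs=0.05)

    def test_extreme_z_clamps_at_cap(self):
        # amplitude 0 under control mean 8.67, SD 0.12 -> z = 72.25
        assert transform_press_amp_z(72.25, C) == 20.0

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=500.0))
    def test_bounded_and_identity_on_lower_branch(self, z):
        tz = transform_press_amp_z(z, C)
        assert 0.0 <= tz <= 20.0 + 1e-12 or tz == z
        if z <= 10.0:
            assert tz == z
        else:
            assert tz <= 20.0

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=99.0), st.floats(min_value=1e-6, max_value=1.0))
    def test_monotone_non_decreasing(self, z, dz):
        assert transform_press_amp_z(z + dz, C) >= transform_press_amp_z(z, C) - 1e-12


class TestMobilityScore:
    def zmap(self, z):
        return {m: z for m in MOBILITY_METRICS}

    def test_all_zero_is_perfect(self):
        assert mobility_score(self.zmap(0.0), C) == 100.0

    def test_unit_z_scores_give_86(self):
        assert mobility_score(self.zmap(1.0), C) == pytest.approx(86.0)

    def test_floor_clamps_at_zero(self):
        assert mobility_score(self.zmap(8.0), C) == 0.0

    def test_missing_metric_named_in_error(self):
        zm = self.zmap(1.0)
        del zm["isi_cv"]
        with pytest.raises(ScoringError, match="isi_cv"):
            mobility_score(zm, C)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=12.0), st.floats(min_value=0.0, max_value=2.0))
    def test_monotone_non_increasing_in_each_z(self, z, dz):
        zm = self.zmap(z)
        base = mobility_score(zm, C)
        zm["press_speed_mm_s"] = z + dz
        assert mobility_score(zm, C) <= base + 1e-9


class TestTremorSeverity:
    def test_zero_tremor_scores_zero(self):
        assert tremor_severity(0.0, [], C) == 0.0

    def test_half_max_amplitude_at_20_percent(self):
        # 20 + 100 * (1/2)^2 = 45; no suppression at pct >= 10
        amps = [C.amp_max_mm / 2] * 8
        assert tremor_severity(20.0, amps, C) == pytest.approx(45.0)

    def test_published_style_example(self):
        # 18% tremor at uniform 5.7 mm with AmpMax 12.5 -> ~38.8
        val = tremor_severity(18.0, [5.7] * 10, C)
        assert val == pytest.approx(18.0 + 100 * (5.7 / 12.5) ** 2, abs=1e-9)

    def test_low_percent_suppression_factor(self):
        # at pct just below 10 the scale factor is 4^(0.5-1) = 0.5
        amps = [6.25] * 4
        unsuppressed = 100 * (6.25 / 12.5) ** 2
        val = tremor_severity(9.999, amps, C)
        assert val == pytest.approx(9.999 + unsuppressed * 4 ** (0.05 * 9.999 - 1), rel=1e-6)
        assert tremor_severity(10.0, amps, C) == pytest.approx(10.0 + unsuppressed)

    def test_suppression_modes(self):
        amps = [5.0]
        pct = 5.0
        factor = 4 ** (0.05 * pct - 1)
        comp = 100 * (5.0 / 12.5) ** 2
        assert tremor_severity(pct, amps, C, "off") == pytest.approx(pct + comp)
        assert tremor_severity(pct, amps, C, "scale") == pytest.approx(pct + comp * factor)
        assert tremor_severity(pct, amps, C, "replace") == pytest.approx(pct + 100 * factor**2)

    def test_amplitude_above_device_max_rejected(self):
        with pytest.raises(ParameterError):
            tremor_severity(20.0, [13.0], C)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=99.0), st.floats(min_value=0.01, max_value=1.0))
    def test_monotone_in_percent(self, pct, dp):
        amps = [4.0, 5.0]
        assert tremor_severity(min(pct + dp, 100.0), amps, C) >= tremor_severity(pct, amps, C) - 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=11.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_amplitudes(self, amp, da):
        pct = 15.0
        hi = min(amp + da, C.amp_max_mm)
        assert tremor_severity(pct, [hi, 3.0], C) >= tremor_severity(pct, [amp, 3.0], C) - 1e-9


class TestFlags:
    entry_low = MetricReference(8.67, 0.12, "lower_worse", 8.59, "lower")
    entry_high = MetricReference(0.05, 0.01, "higher_worse", 0.056, "upper")

    def test_value_at_threshold_is_normal(self):
        assert flag_metric(8.59, self.entry_low) == "normal"
        assert flag_metric(0.056, self.entry_high) == "normal"

    def test_far_below_control_distribution_is_abnormal(self):
        assert flag_metric(2.0, self.entry_low) == "abnormal"

    def test_median_value_is_normal(self):
        assert flag_metric(8.67, self.entry_low) == "normal"
        assert flag_metric(0.05, self.entry_high) == "normal"

    def test_unknown_metric_is_reference_error(self, reference):
        with pytest.raises(ReferenceError_, match="unknown"):
            reference["no_such_metric"]


class TestBuildReference:
    def test_constant_metric_column_rejected(self):
        table = simulate_control_cohort(20, seed=0, trace_based=False)
        table["isi_cv"] = 0.05
        with pytest.raises(ReferenceError_, match="zero SD"):
            build_reference(table)

    def test_single_subject_rejected(self):
        table = simulate_control_cohort(20, seed=0, trace_based=False)
        table["subject_id"] = "only_one"
        with pytest.raises(ReferenceError_, match="2 control subjects"):
            build_reference(table)

    def test_small_cohort_warns(self):
        table = simulate_control_cohort(5, seed=0, trace_based=False)
        with pytest.warns(UserWarning, match="unstable"):
            build_reference(table)

    def test_uniform_age_cohort_skips_age_slopes(self):
        table = simulate_control_cohort(20, seed=0, trace_based=False)
        table["age_years"] = 60.0
        ref = build_reference(table)
        assert all(ref[m].age_slope is None for m in ref.metrics)

    def test_age_slopes_fitted_for_the_three_age_metrics(self, reference):
        with_slope = {m for m, e in reference.metrics.items() if e.age_slope is not None}
        assert with_slope == {"press_amplitude_cv", "release_slope_mm_s", "press_speed_mm_s"}

    def test_thresholds_sit_at_the_quartiles(self):
        table = simulate_control_cohort(2000, seed=1, trace_based=False)
        ref = build_reference(table)
        # on a large cohort the 25th/75th percentile thresholds flag ~25%
        for m in ("press_amplitude_mm", "isi_cv"):
            vals = table[m].to_numpy()
            adj = vals if ref[m].age_slope is None else (
                vals - ref[m].age_slope * (table["age_years"].to_numpy() - 60.0)
            )
            frac = np.mean([flag_metric(v, ref[m]) == "abnormal" for v in adj])
            assert 0.22 <= frac <= 0.28

    def test_json_round_trip(self, reference, tmp_path):
        p = tmp_path / "ref.json"
        reference.to_json(p)
        back = NormativeReference.from_json(p)
        assert back.metrics == reference.metrics
        assert back.constants == reference.constants
        assert back.synthetic == reference.synthetic


class TestScorePanel:
    def make_control_mean_metrics(self, reference):
        vals = {m: reference[m].mean for m in reference.metrics if m != "mobility_score"}
        return HandMetrics(
            press_amplitude_mm=vals["press_amplitude_mm"],
            press_amplitude_cv=vals["press_amplitude_cv"],
            isi_s=vals["isi_s"],
            isi_cv=vals["isi_cv"],
            press_speed_mm_s=vals["press_speed_mm_s"],
            release_slope_mm_s=vals["release_slope_mm_s"],
            dwell_time_s=0.08,
            rest_tremor_pct=0.0,
            taps_per_minute=vals["taps_per_minute"],
            n_voluntary_strikes=100,
        )

    def test_control_mean_vector_scores_100(self, reference):
        hm = self.make_control_mean_metrics(reference)
        panel = score_panel(hm, reference)
        assert panel.mobility_score == 100.0
        assert all(m.directional_z == 0.0 for m in panel.metrics.values())
        assert panel.tremor_severity == 0.0

    def test_panel_invariants(self, reference):
        hm = self.make_control_mean_metrics(reference)
        hm.press_amplitude_mm = 5.0
        hm.isi_s = 0.8
        hm.rest_tremor_pct = 12.0
        panel = score_panel(hm, reference, tremor_amplitudes_mm=[2.0, 2.5])
        assert 0.0 <= panel.mobility_score <= 100.0
        assert all(m.directional_z >= 0.0 for m in panel.metrics.values())
        assert panel.tremor_severity > 12.0
        assert panel.metrics["press_amplitude_mm"].flag == "abnormal"

    def test_incomplete_metrics_cannot_be_scored(self, reference):
        with pytest.raises(ScoringError, match="incomplete"):
            score_panel(HandMetrics(), reference)
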