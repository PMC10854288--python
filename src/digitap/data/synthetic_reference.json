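{
 "schema_version": 1,
 "kind": "digitap-normative-reference",
 "synthetic": true,
 "n_subjects": 100,
 "constants": {
  "amp_max_mm": 12.5,
  "reference_age_years": 60.0,
  "mobility_scale": 14.0,
  "mobility_n": 6,
  "pa_transform_A": 3.2,
  "pa_transform_k": 0.495,
  "pa_z_transition": 10.0,
  "pa_z_cap": 20.0,
  "rt_A": 4.0,
  "rt_k": 0.05,
  "rt_b": -1.0,
  "low_tremor_pct_threshold": 10.0
 },
 "metrics": {
  "isi_cv": {
   "mean": 0.04965525946776736,
   "sd": 0.010327375801656455,
   "direction": "higher_worse",
   "threshold": 0.0560362740723654,
   "threshold_side": "upper",
   "age_slope": null
  },
  "isi_s": {
   "mean": 0.49698395366705483,
   "sd": 0.03848793679781646,
   "direction": "higher_worse",
   "threshold": 0.5197354213074263,
   "threshold_side": "upper",
   "age_slope": null
  },
  "press_amplitude_cv": {
   "mean": 0.030911740397849042,
   "sd": 0.006840186064131554,
   "direction": "higher_worse",
   "threshold": 0.03528791042224014,
   "threshold_side": "upper",
   "age_slope": 0.0008461159556440933
  },
  "press_amplitude_mm": {
   "mean": 8.650607447834563,
   "sd": 0.12387552304345811,
   "direction": "lower_worse",
   "threshold": 8.554346097245716,
   "threshold_side": "lower",
   "age_slope": null
  },
  "press_speed_mm_s": {
   "mean": 72.15849181716422,
   "sd": 6.223476969672581,
   "direction": "lower_worse",
   "threshold": 66.97421912318694,
   "threshold_side": "lower",
   "age_slope": -0.2161011175352146
  },
  "release_slope_mm_s": {
   "mean": 72.89067574420382,
   "sd": 6.3231338208879695,
   "direction": "lower_worse",
   "threshold": 68.39003316278061,
   "threshold_side": "lower",
   "age_slope": -0.3560583432282035
  },
  "taps_per_minute": {
   "mean": 237.56,
   "sd": 18.570270582168412,
   "direction": "lower_worse",
   "threshold": 226.0,
   "threshold_side": "lower",
   "age_slope": null
  },
  "mobility_score": {
   "mean": 94.37940821699743,
   "sd": 3.135128271190517,
   "direction": "lower_worse",
   "threshold": 92.7568439029616,
   "threshold_side": "lower",
   "age_slope": null
  }
 }
}
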