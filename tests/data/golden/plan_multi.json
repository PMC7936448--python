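{
  "determinative_site": "M04",
  "period_unit": "week",
  "sites": [
    {
      "ci_high": 24.60475,
      "ci_low": 24.32675,
      "delay": 0,
      "determinative": false,
      "end_period": 24.46575,
      "goal": 60,
      "mean_duration": 24.46575,
      "rate": 2.5,
      "site_id": "M01"
    },
    {
      "ci_high": 50.88228,
      "ci_low": 50.40722,
      "delay": 0,
      "determinative": false,
      "end_period": 50.64475,
      "goal": 60,
      "mean_duration": 50.64475,
      "rate": 1.2,
      "site_id": "M02"
    },
    {
      "ci_high": 30.597071,
      "ci_low": 30.377929,
      "delay": 2,
      "determinative": false,
      "end_period": 32.4875,
      "goal": 90,
      "mean_duration": 30.4875,
      "rate": 3.0,
      "site_id": "M03"
    },
    {
      "ci_high": 67.596517,
      "ci_low": 66.982983,
      "delay": 0,
      "determinative": true,
      "end_period": 67.28975,
      "goal": 40,
      "mean_duration": 67.28975,
      "rate": 0.6,
      "site_id": "M04"
    }
  ],
  "trial_ci_high": 68.030122,
  "trial_ci_low": 67.440878,
  "trial_duration": 67.28975
}
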