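{
  "cumulative_series": [
    4,
    9,
    17,
    23,
    34,
    40,
    44,
    46,
    51,
    60,
    68,
    81,
    86,
    91,
    96,
    97,
    110,
    116,
    120,
    126,
    131,
    141,
    144,
    149,
    156,
    163,
    166,
    177,
    181,
    188
  ],
  "current_period": 30,
  "determinant_site": "M04",
  "expected_end_period": 75.4935,
  "flagged_sites": [
    "M02",
    "M04"
  ],
  "sites": [
    {
      "complete": true,
      "goal": 60,
      "lat": -33.92,
      "lon": 18.42,
      "rate_hat": 2.166667,
      "recruited": 65,
      "remaining": 0,
      "remaining_ci_high": 0.0,
      "remaining_ci_low": 0.0,
      "remaining_mean": 0.0,
      "site_id": "M01",
      "stalled": false
    },
    {
      "complete": false,
      "goal": 60,
      "lat": -33.58,
      "lon": 22.2,
      "rate_hat": 0.9,
      "recruited": 27,
      "remaining": 33,
      "remaining_ci_high": 37.541658,
      "remaining_ci_low": 37.113342,
      "remaining_mean": 37.3275,
      "site_id": "M02",
      "stalled": false
    },
    {
      "complete": false,
      "goal": 90,
      "lat": -29.85,
      "lon": 31.02,
      "rate_hat": 2.857143,
      "recruited": 80,
      "remaining": 10,
      "remaining_ci_high": 4.023572,
      "remaining_ci_low": 3.954428,
      "remaining_mean": 3.989,
      "site_id": "M03",
      "stalled": false
    },
    {
      "complete": false,
      "goal": 40,
      "lat": -26.2,
      "lon": 28.05,
      "rate_hat": 0.533333,
      "recruited": 16,
      "remaining": 24,
      "remaining_ci_high": 45.758866,
      "remaining_ci_low": 45.228134,
      "remaining_mean": 45.4935,
      "site_id": "M04",
      "stalled": false
    }
  ],
  "threshold": 30,
  "total_recruited": 188,
  "warnings": []
}
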