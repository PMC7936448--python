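{
  "bins": [
    {
      "category": "0",
      "expected": 6.015531,
      "observed": 4
    },
    {
      "category": "1",
      "expected": 13.83572,
      "observed": 16
    },
    {
      "category": "2",
      "expected": 15.911078,
      "observed": 16
    },
    {
      "category": "3",
      "expected": 12.198494,
      "observed": 14
    },
    {
      "category": "4",
      "expected": 7.014134,
      "observed": 4
    },
    {
      "category": ">=5",
      "expected": 5.025043,
      "observed": 6
    }
  ],
  "df": 4,
  "n_periods": 60,
  "p_value": 0.597921,
  "rate_hat": 2.3,
  "site_id": "G01",
  "statistic": 2.764816
}
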