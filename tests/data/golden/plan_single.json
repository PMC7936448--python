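{
  "ci_high": 20.584261,
  "ci_low": 20.308239,
  "delay": 0,
  "end_period": 20.44625,
  "goal": 50,
  "mean_duration": 20.44625,
  "rate": 2.5
}
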