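category  observed  expected
       0         4  6.015531
       1        16 13.835720
       2        16 15.911078
       3        14 12.198494
       4         4  7.014134
     >=5         6  5.025043
rate_hat = 2.3000 over 60 periods
chi-squared = 2.7648, df = 4, p = 0.5979
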