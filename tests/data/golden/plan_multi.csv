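site_id,goal,rate,delay,mean_duration,ci_low,ci_high,end_period,determinative
M01,60,2.5,0,24.46575,24.32675,24.60475,24.46575,False
M02,60,1.2,0,50.64475,50.40722,50.88228,50.64475,False
M03,90,3.0,2,30.4875,30.377929,30.597071,32.4875,False
M04,40,0.6,0,67.28975,66.982983,67.596517,67.28975,True
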