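site_id,goal,rate,delay,start_date,lat,lon
M01,60,2.5,0,2021-01-04,-33.92,18.42
M02,60,1.2,0,2021-01-04,-33.58,22.2
M03,90,3.0,2,2021-01-18,-29.85,31.02
M04,40,0.6,0,2021-01-04,-26.2,28.05
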