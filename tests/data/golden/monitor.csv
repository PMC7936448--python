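site_id,goal,recruited,remaining,rate_hat,remaining_mean,remaining_ci_low,remaining_ci_high,complete,stalled,lat,lon
M01,60,65,0,2.166667,0.0,0.0,0.0,True,False,-33.92,18.42
M02,60,27,33,0.9,37.3275,37.113342,37.541658,False,False,-33.58,22.2
M03,90,80,10,2.857143,3.989,3.954428,4.023572,False,False,-29.85,31.02
M04,40,16,24,0.533333,45.4935,45.228134,45.758866,False,False,-26.2,28.05
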