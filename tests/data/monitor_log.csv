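site_id,date,count
M01,2021-01-04,1
M02,2021-01-04,1
M02,2021-01-05,1
M01,2021-01-10,1
M01,2021-01-16,1
M02,2021-01-16,1
M04,2021-01-16,1
M01,2021-01-17,2
M02,2021-01-19,1
M03,2021-01-20,1
M01,2021-01-22,1
M03,2021-01-22,2
M01,2021-01-23,1
M01,2021-01-24,1
M03,2021-01-24,1
M01,2021-01-28,1
M01,2021-01-30,1
M03,2021-01-30,1
M02,2021-01-31,1
M03,2021-01-31,2
M02,2021-02-01,1
M03,2021-02-03,1
M01,2021-02-04,1
M03,2021-02-04,2
M03,2021-02-05,2
M01,2021-02-06,1
M01,2021-02-07,2
M03,2021-02-07,1
M02,2021-02-08,1
M03,2021-02-09,1
M01,2021-02-11,1
M02,2021-02-11,1
M01,2021-02-13,1
M03,2021-02-13,1
M01,2021-02-16,1
M03,2021-02-16,1
M03,2021-02-19,1
M01,2021-02-20,1
M02,2021-02-24,1
M03,2021-02-26,1
M03,2021-03-03,1
M04,2021-03-04,1
M01,2021-03-05,1
M03,2021-03-05,1
M03,2021-03-06,1
M01,2021-03-08,1
M03,2021-03-08,1
M02,2021-03-09,1
M03,2021-03-09,1
M04,2021-03-09,1
M03,2021-03-10,1
M01,2021-03-11,1
M01,2021-03-13,1
M01,2021-03-14,1
M01,2021-03-16,1
M03,2021-03-16,1
M01,2021-03-17,2
M03,2021-03-18,1
M01,2021-03-19,1
M03,2021-03-19,1
M03,2021-03-21,1
M03,2021-03-22,1
M03,2021-03-23,2
M02,2021-03-24,1
M03,2021-03-24,1
M01,2021-03-25,1
M02,2021-03-25,1
M03,2021-03-25,3
M01,2021-03-27,1
M04,2021-03-27,1
M01,2021-03-28,1
M01,2021-03-29,1
M04,2021-03-31,1
M01,2021-04-01,1
M03,2021-04-04,2
M02,2021-04-06,1
M03,2021-04-07,1
M03,2021-04-08,1
M01,2021-04-10,1
M03,2021-04-10,1
M01,2021-04-12,1
M03,2021-04-13,1
M01,2021-04-14,1
M01,2021-04-18,2
M04,2021-04-25,1
M01,2021-04-26,1
M03,2021-04-26,1
M01,2021-04-29,1
M02,2021-04-29,1
M03,2021-04-29,2
M01,2021-04-30,1
M02,2021-04-30,1
M03,2021-04-30,1
M02,2021-05-01,1
M01,2021-05-02,1
M02,2021-05-02,2
M01,2021-05-03,1
M03,2021-05-04,1
M03,2021-05-06,1
M01,2021-05-08,1
M01,2021-05-09,2
M04,2021-05-10,1
M03,2021-05-11,1
M03,2021-05-13,1
M03,2021-05-14,1
M02,2021-05-17,1
M03,2021-05-17,1
M01,2021-05-19,1
M01,2021-05-20,1
M01,2021-05-22,1
M03,2021-05-22,1
M03,2021-05-26,1
M04,2021-05-26,1
M03,2021-05-28,1
M04,2021-05-28,1
M01,2021-05-30,1
M01,2021-05-31,1
M03,2021-06-01,1
M01,2021-06-03,1
M03,2021-06-03,1
M01,2021-06-05,1
M03,2021-06-05,1
M04,2021-06-05,1
M02,2021-06-06,1
M03,2021-06-06,2
M02,2021-06-08,1
M02,2021-06-10,1
M03,2021-06-13,1
M01,2021-06-14,1
M03,2021-06-17,1
M03,2021-06-18,1
M01,2021-06-19,1
M04,2021-06-19,1
M01,2021-06-23,1
M03,2021-06-23,1
M01,2021-06-24,1
M02,2021-06-24,1
M03,2021-06-24,1
M03,2021-06-25,1
M03,2021-06-26,1
M03,2021-06-28,1
M01,2021-06-29,1
M01,2021-06-30,1
M03,2021-07-01,2
M04,2021-07-01,1
M04,2021-07-03,1
M01,2021-07-08,1
M01,2021-07-09,1
M02,2021-07-09,1
M03,2021-07-12,1
M03,2021-07-13,1
M01,2021-07-14,1
M03,2021-07-14,2
M04,2021-07-14,2
M03,2021-07-15,1
M02,2021-07-16,1
M01,2021-07-17,1
M04,2021-07-17,1
M01,2021-07-20,1
M03,2021-07-20,1
M03,2021-07-23,2
M01,2021-07-26,1
M03,2021-07-27,1
M03,2021-07-29,1
M02,2021-07-30,1
M01,2021-07-31,1
M02,2021-07-31,1
M03,2021-07-31,1
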