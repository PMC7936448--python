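site_id,date,count
G01,2021-01-04,1
G01,2021-01-06,1
G01,2021-01-23,1
G01,2021-01-29,1
G01,2021-01-31,1
G01,2021-02-02,1
G01,2021-02-03,1
G01,2021-02-05,1
G01,2021-02-06,1
G01,2021-02-11,2
G01,2021-02-14,1
G01,2021-02-17,2
G01,2021-02-20,1
G01,2021-02-24,1
G01,2021-02-27,1
G01,2021-03-01,1
G01,2021-03-08,1
G01,2021-03-09,3
G01,2021-03-12,1
G01,2021-03-13,1
G01,2021-03-19,1
G01,2021-03-23,1
G01,2021-03-26,1
G01,2021-03-27,1
G01,2021-03-31,3
G01,2021-04-05,1
G01,2021-04-07,1
G01,2021-04-08,1
G01,2021-04-15,2
G01,2021-04-17,1
G01,2021-04-19,2
G01,2021-04-23,1
G01,2021-04-24,1
G01,2021-04-25,1
G01,2021-04-27,1
G01,2021-04-29,1
G01,2021-05-01,1
G01,2021-05-02,1
G01,2021-05-04,1
G01,2021-05-16,1
G01,2021-05-24,1
G01,2021-05-29,1
G01,2021-06-05,1
G01,2021-06-10,1
G01,2021-06-12,2
G01,2021-06-19,1
G01,2021-06-24,1
G01,2021-06-26,1
G01,2021-07-01,1
G01,2021-07-11,2
G01,2021-07-15,2
G01,2021-07-17,1
G01,2021-07-21,1
G01,2021-07-27,2
G01,2021-07-29,1
G01,2021-07-30,1
G01,2021-08-01,2
G01,2021-08-08,1
G01,2021-08-11,1
G01,2021-08-15,1
G01,2021-08-16,1
G01,2021-08-19,1
G01,2021-08-21,1
G01,2021-08-22,2
G01,2021-08-29,2
G01,2021-09-06,1
G01,2021-09-10,1
G01,2021-09-11,1
G01,2021-09-16,2
G01,2021-09-17,1
G01,2021-09-19,1
G01,2021-09-22,1
G01,2021-09-25,1
G01,2021-09-27,1
G01,2021-09-29,1
G01,2021-10-01,1
G01,2021-10-11,1
G01,2021-10-21,1
G01,2021-10-22,1
G01,2021-10-25,2
G01,2021-11-02,1
G01,2021-11-04,1
G01,2021-11-14,1
G01,2021-11-17,1
G01,2021-11-18,1
G01,2021-11-19,1
G01,2021-11-24,1
G01,2021-11-28,1
G01,2021-11-29,2
G01,2021-12-01,1
G01,2021-12-02,1
G01,2021-12-03,1
G01,2021-12-10,1
G01,2021-12-13,2
G01,2021-12-14,2
G01,2021-12-17,1
G01,2021-12-22,1
G01,2022-01-01,2
G01,2022-01-04,2
G01,2022-01-08,1
G01,2022-01-09,1
G01,2022-01-11,1
G01,2022-01-18,1
G01,2022-01-20,1
G01,2022-01-23,1
G01,2022-01-28,1
G01,2022-02-03,1
G01,2022-02-04,1
G01,2022-02-08,1
G01,2022-02-10,2
G01,2022-02-16,1
G01,2022-02-18,1
G01,2022-02-26,2
G01,2022-02-27,1
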