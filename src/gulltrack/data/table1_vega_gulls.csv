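bird_id,site,age_class,sex,tag_model,start_date,end_date,n_days,n_fixes,duty_cycle_fixes_per_day,total_track_km,mean_km_per_day,longest_gc_km,summering_class
ke1511,Samcheok,immature,male,WT-200,2015-02-25,2015-10-26,243,487,2,6473,26.6,2252,OBR
ke1512,Samcheok,adult,female,WT-200,2015-02-25,2015-11-19,267,534,2,12447,46.6,4123,BR
ke1513,Samcheok,adult,male,WT-200,2015-02-25,2015-07-22,147,286,2,1860,12.7,609,OBR
ke1514,Samcheok,adult,male,WT-200,2015-02-25,2015-10-29,246,493,2,13022,52.9,4226,BR
br1425,Samcheok,adult,male,WT-200/300,2015-02-25,2016-11-15,629,5041,2/12,16349,26.0,3958,BR
br1428,Samcheok,adult,male,WT-200,2015-02-25,2015-10-02,219,439,2,16480,75.3,4232,BR
br1429,Samcheok,adult,female,WT-200,2015-02-25,2016-05-11,441,885,2,18846,42.7,4019,BR
br1430,Samcheok,adult,female,WT-200,2015-02-25,2015-11-22,270,540,2,12596,46.7,3666,BR
vt15079,Samcheok,adult,unknown,WT-300,2015-11-09,2017-05-05,543,6457,12,26282,48.4,4341,BR
vt15081,Samcheok,adult,unknown,WT-300,2015-11-09,2017-05-11,549,4734,12,27155,49.5,4346,BR
vt15088,Samcheok,adult,unknown,WT-300,2015-11-09,2016-04-15,158,2103,12,10908,69.0,3402,OBR
br1530,Samcheok,immature,unknown,WT-300 Mallard,2016-02-16,2017-04-30,439,2661,6,20459,46.6,3367,OBR
br1541,Samcheok,adult,unknown,WT-300 Mallard,2016-02-18,2018-05-14,816,3776,6,42615,52.2,4286,BR
vt16247,Yeongdeok,adult,unknown,WT-300,2017-02-13,2018-10-10,604,6866,12,29933,49.6,4009,BR
vt16249,Yeongdeok,adult,unknown,WT-300,2017-02-13,2017-05-30,106,1237,12,8470,79.9,3428,BR
vt16250,Yeongdeok,adult,unknown,WT-300,2017-02-13,2019-02-19,736,8740,12,38211,51.9,4106,BR
vt16251,Yeongdeok,adult,unknown,WT-300,2017-02-13,2017-05-27,103,1197,12,7491,72.7,3254,BR
vt16252,Yeongdeok,adult,unknown,WT-300,2017-02-13,2019-04-27,803,9551,12,46484,57.9,3974,BR
vt16254,Yeongdeok,adult,unknown,WT-300,2017-02-13,2017-06-06,113,1263,12,5631,49.8,2187,OBR
vt16260,Yeongdeok,immature,unknown,WT-300,2017-02-13,2017-06-25,132,1532,12,7357,55.7,3263,OBR
vt16261,Yeongdeok,immature,unknown,WT-300,2017-02-13,2017-09-19,218,2615,12,6965,31.9,2230,OBR
bpn1721,ChaunDelta,adult,male,WT-300,2017-07-24,2019-12-31,890,9912,12,51010,57.3,4942,BR
bpn1723,ChaunDelta,adult,male,WT-300,2017-07-22,2018-05-10,292,3487,12,10901,37.3,4108,BR
rcees1809,ChaunDelta,adult,female,WT-300,2018-06-28,2019-12-31,551,5988,12,30490,55.3,4738,BR
rcees1811,ChaunDelta,adult,female,WT-300,2018-06-28,2019-05-29,335,3676,12,20275,60.5,4840,BR
rcees1812,ChaunDelta,adult,male,WT-300,2018-06-28,2019-12-31,551,6581,12,19505,35.4,4327,OBR+BR
bpn1910,ChaunDelta,adult,female,WT-300 Buzzard,2019-06-23,2019-11-14,144,1783,12,8440,58.6,3512,BR
bpn1911,ChaunDelta,adult,female,WT-300 Buzzard,2019-06-23,2019-12-31,191,1153,12,7185,37.6,4114,BR
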