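participant_id,thigh_min,imu_min,verbal_min,event_span_avg_min,entries,consensus_min
P1,9990,3381,1113,16,69,915
P2,9958,4183,1707,20,86,1351
P3,9908,4869,1843,14,133,1384
P4,9382,4581,1128,16,71,957
P5,10001,5253,1921,17,112,1270
P6,11032,5382,3700,14,261,3420
P7,9947,3377,1960,27,72,1619
P8,9936,3692,1317,14,96,895
P9,9981,4391,2690,53,51,1972
P10,9360,4754,1332,15,89,1022
P11,7552,3675,1701,45,38,1260
P12,9837,3955,2050,30,69,1580
P13,9953,4976,2339,25,94,1650
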