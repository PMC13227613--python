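activity,thigh_min,thigh_labeled_imu_min,verbal_labeled_imu_min,consensus_min
Lying,43940,1612,918,315
SittingNotInTransport,47230,28898,9935,10187
SittingInTransport,4535,3897,2058,1728
Standing,24981,16044,1190,4940
LowStepping,4493,3138,122,1157
ModerateStepping,1360,1142,759,786
VigorousStepping,65,65,99,56
Cycling,233,201,264,126
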