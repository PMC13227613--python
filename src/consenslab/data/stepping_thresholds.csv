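participant_id,theta_lm,theta_mv
P1,80,
P2,100,
P3,80,
P4,90,
P5,100,135
P6,80,
P7,80,
P8,80,
P9,90,
P10,90,
P11,90,
P12,85,
P13,90,130
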