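style,count
C1,440
C2,297
C3,259
C4,87
C5,69
C6,59
C7,47
I1,52
I2,33
I3,14
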