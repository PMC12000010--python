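subject,pca,ica,ccca
S1,0.4375,0.2708,0.1875
S2,0.2708,0.1458,0.1458
S3,0.3750,0.3333,0.3333
S4,0.3542,0.3750,0.1458
S6,0.3750,0.3125,0.2500
S7,0.1458,0.2500,0.2708
S8,0.2708,0.2292,0.2292
S9,0.1250,0.1250,0.1667
S10,0.2708,0.3333,0.4167
S11,0.0833,0.1875,0.1250
S12,0.2292,0.3333,0.3333
S13,0.2917,0.2917,0.1667
S14,0.6250,0.7083,0.6875
S15,0.2500,0.4167,0.6250
S16,0.2083,0.2292,0.1667
S17,0.5000,0.3750,0.2292
S18,0.3750,0.3125,0.2083
S19,0.1667,0.2083,0.1250
S20,0.3542,0.1875,0.2500
S21,0.2083,0.1667,0.1667
S22,0.3333,0.4375,0.5833
S23,0.1667,0.1667,0.1042
S24,0.3125,0.2500,0.3958
S25,0.2083,0.5417,0.5625
S26,0.2708,0.4167,0.7292
S27,0.2500,0.2500,0.1458
S28,0.3333,0.1250,0.1875
S29,0.1042,0.2917,0.1458
S30,0.1875,0.1042,0.2083
S31,0.6250,0.5208,0.4375
S32,0.4167,0.3333,0.3958
S33,0.1042,0.1458,0.1250
S34,0.5625,0.4167,0.6250
S35,0.2292,0.3125,0.4167
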