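# Monte-Carlo calibration: phase-jitter SD -> mean measured PLV
# defaults: 3 Hz shared oscillator, 120 s SWS segments, 8 seeds
jitter_sd,plv
0.0,0.9281
0.15,0.9098
0.3,0.8553
0.45,0.7699
0.6,0.6643
0.75,0.5476
0.9,0.4302
1.05,0.3248
1.2,0.2367
1.35,0.1710
1.5,0.1255
1.65,0.0943
1.8,0.0805
1.95,0.0701
2.1,0.0622
2.25,0.0588
2.4,0.0557
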