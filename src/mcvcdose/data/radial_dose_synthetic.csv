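r_cm,g
0.1,0.994086
0.15,0.994608
0.25,0.995582
0.5,0.997622
0.75,0.999093
1,1.000000
1.5,1.000131
2,0.998052
2.5,0.993813
3,0.987479
4,0.968846
5,0.942895
6,0.910510
8,0.830398
10,0.736718
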