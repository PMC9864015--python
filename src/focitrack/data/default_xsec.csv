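energy_ev,imfp_elastic,imfp_ionization,imfp_excitation
1.0,0.50,0.0,0.0
5.0,0.80,0.0,0.0
7.4,0.90,0.0,0.0
8.0,0.95,0.0,0.02
10.0,1.00,0.0,0.05
15.0,1.10,0.08,0.12
20.0,1.20,0.18,0.15
30.0,1.10,0.30,0.15
50.0,0.90,0.40,0.13
100.0,0.60,0.42,0.10
200.0,0.40,0.33,0.07
500.0,0.22,0.20,0.040
1000.0,0.13,0.125,0.025
2000.0,0.075,0.075,0.014
5000.0,0.035,0.036,0.0065
10000.0,0.020,0.0205,0.0036
20000.0,0.011,0.0115,0.0020
50000.0,0.005,0.0052,0.0009
100000.0,0.003,0.0029,0.0005
1000000.0,0.0005,0.0004,0.00007
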