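energy_keV,muen_rho
5,39.31
5.5,29.5003
6,22.7
6.5,17.784
7,14.1882
7.5,11.4981
8,9.446
8.5,7.83228
9,6.56465
9.5,5.55535
10,4.742
11,3.51747
12,2.67859
13,2.08533
14,1.65435
15,1.334
16,1.08761
17,0.898102
18,0.75008
19,0.632865
20,0.5389
21,0.461806
22,0.398819
23,0.346888
24,0.303717
25,0.267555
26,0.237055
28,0.189057
30,0.1537
33,0.115954
36,0.0905594
40,0.0683
45,0.05125
50,0.041
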