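scenario_id,label,b_bar,sigma_ad,sigma_ai,sigma_a_gr
1,competition,-0.05,0.015,0.015,1.0
2,neutral,0.0,0.015,0.015,1.0
3,cooperation,0.05,0.015,0.015,1.0
4,competition,-0.05,0.045,0.015,1.0
5,neutral,0.0,0.045,0.015,1.0
6,cooperation,0.05,0.045,0.015,1.0
7,competition,-0.05,0.005,0.015,1.0
8,neutral,0.0,0.005,0.015,1.0
9,cooperation,0.05,0.005,0.015,1.0
10,competition,-0.05,0.015,0.045,1.0
11,neutral,0.0,0.015,0.045,1.0
12,cooperation,0.05,0.015,0.045,1.0
13,competition,-0.05,0.015,0.005,1.0
14,neutral,0.0,0.015,0.005,1.0
15,cooperation,0.05,0.015,0.005,1.0
16,competition,-0.05,0.015,0.015,3.0
17,neutral,0.0,0.015,0.015,3.0
18,cooperation,0.05,0.015,0.015,3.0
19,competition,-0.05,0.015,0.015,0.3
20,neutral,0.0,0.015,0.015,0.3
21,cooperation,0.05,0.015,0.015,0.3
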