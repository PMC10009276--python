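# Intracellular ATP (mmol/L) vs time since occlusion (min).
# Control points constructed from guinea-pig whole-heart ischemia literature;
# normoxic anchor 10 mmol/L.
t_min,value
0.0,10.0
1.0,9.4
2.5,8.5
5.0,7.0
7.5,5.9
10.0,5.0
12.5,4.55
15.0,4.2
20.0,3.6
25.0,3.1
30.0,2.7
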