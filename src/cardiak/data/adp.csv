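# Free intracellular ADP (umol/L) vs time since occlusion (min).
# Biphasic course (rapid rise, mild late decline); normoxic anchor 15 umol/L.
t_min,value
0.0,15.0
1.0,26.0
2.0,40.0
3.0,55.0
4.0,70.0
5.0,81.0
6.0,90.0
7.0,96.0
8.0,99.0
10.0,100.0
12.0,99.0
15.0,96.0
20.0,90.0
25.0,85.0
30.0,80.0
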