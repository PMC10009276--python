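# Alternative, slower monotone ADP (umol/L) profile for sensitivity runs.
t_min,value
0.0,15.0
5.0,30.0
10.0,50.0
15.0,65.0
20.0,75.0
25.0,82.0
30.0,88.0
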