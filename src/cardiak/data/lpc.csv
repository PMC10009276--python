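# Intracellular lysophosphatidylcholine (umol/L); linear 2 -> 20 over 30 min.
t_min,value
0.0,2.0
30.0,20.0
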