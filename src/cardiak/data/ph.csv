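# Intracellular pH vs time since occlusion (min); pHo follows the same course
# from its own normoxic anchor (7.4), i.e. pHo(t) = 7.4 + (pHi(t) - 7.2).
t_min,value
0.0,7.2
2.0,7.15
5.0,7.05
7.5,6.95
10.0,6.85
15.0,6.70
20.0,6.55
25.0,6.45
30.0,6.40
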