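time_min,ethanol_pct,solvent_ml_per_g,power_w,response
20,70,10,120,9.31
40,60,15,120,3.39
30,60,15,180,2.6
30,50,15,120,3.19
40,60,5,120,9.51
30,70,10,180,6.35
20,60,10,60,3.98
30,50,10,180,7.93
20,60,5,120,5.56
30,60,10,120,9.71
30,50,5,120,6.35
20,60,10,180,6.35
30,60,5,60,3.98
40,50,10,120,9.89
20,50,10,120,5.96
30,60,15,60,2.2
30,60,5,180,6.75
30,70,10,60,5.76
30,60,10,120,10.3
40,70,10,120,7.54
30,60,10,120,10.5
30,50,10,60,2.4
30,60,10,120,10.89
30,70,15,120,4.57
20,60,15,120,5.56
40,60,10,60,6.94
40,60,10,180,9.12
30,70,5,120,6.94
30,60,10,120,10.1
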