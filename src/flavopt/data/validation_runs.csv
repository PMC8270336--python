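model,time_min,ethanol_pct,solvent_ml_per_g,power_w,experiment_pct,prediction_pct
BBD,40,50.9,8.82,148.87,10.5571,11.0688
ANN-GA,38.36,54.69,7.89,175.78,14.0137,13.7512
ANN-PSO,20.21,50,5,101.89,13.2434,12.7832
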