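neuron,w_time,w_ethanol,w_ratio,w_power,input_bias,layer_weight,layer_bias
1,-1.227,1.201,-0.0184,1.803,2.49,0.802,0.46
2,1.174,0.941,-1.143,-1.621,-1.936,0.149,
3,1.569,-0.581,-1.425,1.17,-1.383,0.69,
4,0.097,0.229,2.359,0.757,-0.83,0.477,
5,1.279,-1.365,0.202,1.631,-0.277,0.172,
6,0.374,-1.649,1.824,0.118,0.277,-0.507,
7,-1.595,-1.68,0.908,-0.095,-0.83,0.333,
8,-1.594,0.949,0.44,1.601,-1.383,-0.833,
9,-0.543,-0.028,1.839,-1.587,-1.936,0.252,
10,1.127,-1.406,1.718,-0.009,2.49,0.322,
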