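dataset,OPSO,PSO,MTBO,DE,ACO,CGO,LSHADE,AOA
D1,0.9151,0.8114,0.7375,0.6925,0.6899,0.7886,0.7682,0.7201
D2,0.9598,0.7639,0.7345,0.7112,0.6509,0.7317,0.7840,0.7025
D3,0.9241,0.8707,0.8321,0.8321,0.8264,0.8290,0.8340,0.8288
D4,0.9367,0.8923,0.8601,0.8323,0.8325,0.8575,0.9450,0.9013
D5,0.9208,0.9045,0.8786,0.8786,0.8786,0.8967,0.8110,0.8505
D6,0.9343,0.9198,0.8317,0.8160,0.7931,0.9046,0.8513,0.8234
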