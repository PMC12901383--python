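dataset,OPSO,PSO,MTBO,DE,ACO,CGO,LSHADE,AOA
D1,0.9523,0.8367,0.7895,0.8401,0.8071,0.7255,0.7238,0.8354
D2,0.9591,0.8133,0.7867,0.7432,0.5224,0.6173,0.5680,0.8133
D3,0.9557,0.9194,0.9000,0.8844,0.8418,0.8847,0.8847,0.8857
D4,0.9630,0.9328,0.9167,0.9036,0.8682,0.9039,0.9872,0.9530
D5,0.9414,0.7929,0.7548,0.7779,0.6714,0.7582,0.7371,0.8180
D6,0.9663,0.9122,0.8711,0.8677,0.7847,0.8531,0.8490,0.8687
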