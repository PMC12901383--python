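dataset,OPSO,PSO,MTBO,DE,ACO,CGO,LSHADE,AOA
D1,0.9237,0.7857,0.7286,0.7000,0.7000,0.7571,0.8143,0.7429
D2,0.9591,0.7286,0.7000,0.6571,0.6000,0.7143,0.7286,0.7286
D3,0.9229,0.8429,0.8000,0.8000,0.8000,0.8000,0.8143,0.8000
D4,0.9357,0.8690,0.8333,0.8095,0.8214,0.8333,0.9286,0.9286
D5,0.9214,0.9000,0.8000,0.8000,0.8000,0.8857,0.7857,0.8000
D6,0.9214,0.9143,0.8286,0.8143,0.7857,0.9000,0.9000,0.8429
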