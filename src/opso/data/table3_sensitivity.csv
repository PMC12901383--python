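dataset,OPSO,PSO,MTBO,DE,ACO,CGO,LSHADE,AOA
D1,0.9483,0.9143,0.7714,0.7143,0.8857,0.8857,0.8857,0.8000
D2,0.9429,0.8571,0.8000,0.8000,0.8000,0.8000,0.8857,0.8286
D3,0.9800,1.0000,0.9429,0.9429,0.9714,0.9429,0.9714,0.9714
D4,0.9833,1.0000,0.9524,0.9048,0.9762,0.9524,0.9143,0.9143
D5,0.9686,0.9429,0.7143,0.7143,0.7143,1.0000,0.8000,0.7714
D6,0.9546,0.9714,0.8571,0.8286,0.9143,0.9714,1.0000,0.8857
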