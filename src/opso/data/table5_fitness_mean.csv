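dataset,OPSO,PSO,MTBO,DE,ACO,CGO,LSHADE,AOA
D1,0.1722,0.3392,0.3297,0.3750,0.3791,0.1851,0.2066,0.2883
D2,0.1637,0.1412,0.3053,0.3624,0.3661,0.1677,0.1849,0.2547
D3,0.1123,0.3236,0.2270,0.2728,0.2762,0.1120,0.1383,0.1892
D4,0.0938,0.3007,0.1974,0.2466,0.2500,0.0936,0.0587,0.0605
D5,0.0530,0.2362,0.1398,0.2132,0.2338,0.0443,0.0626,0.0943
D6,0.0542,0.2190,0.2025,0.2642,0.2681,0.0378,0.0507,0.1259
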