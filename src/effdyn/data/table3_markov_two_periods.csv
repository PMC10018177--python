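period,level,sbm_L,sbm_ML,sbm_MH,sbm_H,human_L,human_ML,human_MH,human_H,nonhuman_L,nonhuman_ML,nonhuman_MH,nonhuman_H
2013-2017,L,0.563,0.188,0.188,0.063,0.594,0.375,0.000,0.031,0.563,0.219,0.063,0.156
2013-2017,ML,0.162,0.676,0.081,0.081,0.212,0.424,0.182,0.182,0.163,0.651,0.070,0.116
2013-2017,MH,0.231,0.154,0.308,0.308,0.067,0.100,0.667,0.167,0.167,0.278,0.278,0.278
2013-2017,H,0.034,0.034,0.276,0.655,0.103,0.103,0.103,0.690,0.065,0.097,0.258,0.581
2018-2020,L,0.688,0.250,0.063,0.000,0.667,0.200,0.133,0.000,0.733,0.267,0.000,0.000
2018-2020,ML,0.053,0.632,0.211,0.105,0.176,0.412,0.294,0.118,0.083,0.583,0.167,0.167
2018-2020,MH,0.167,0.083,0.583,0.167,0.000,0.214,0.643,0.143,0.111,0.222,0.222,0.444
2018-2020,H,0.000,0.133,0.067,0.800,0.188,0.063,0.063,0.688,0.071,0.214,0.071,0.643
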