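neighbor_level,level,total_L,total_ML,total_MH,total_H,human_L,human_ML,human_MH,human_H,nonhuman_L,nonhuman_ML,nonhuman_MH,nonhuman_H
L,L,0.500,0.167,0.167,0.167,0.200,0.600,0.000,0.200,0.429,0.143,0.000,0.429
L,ML,0.000,0.833,0.000,0.167,0.000,0.833,0.167,0.000,0.000,1.000,0.000,0.000
L,MH,0.143,0.000,0.714,0.143,0.667,0.000,0.333,0.000,0.000,0.000,1.000,0.000
L,H,0.000,0.000,0.333,0.667,0.333,0.000,0.000,0.667,0.100,0.000,0.300,0.600
ML,L,0.577,0.192,0.192,0.038,0.591,0.318,0.045,0.045,0.640,0.200,0.080,0.080
ML,ML,0.077,0.692,0.115,0.115,0.467,0.333,0.133,0.067,0.106,0.574,0.149,0.170
ML,MH,0.250,0.125,0.375,0.250,0.071,0.143,0.500,0.286,0.125,0.417,0.250,0.208
ML,H,0.077,0.077,0.269,0.577,0.200,0.100,0.000,0.700,0.067,0.167,0.200,0.567
MH,L,0.769,0.154,0.077,0.000,0.769,0.231,0.000,0.000,0.800,0.100,0.000,0.100
MH,ML,0.235,0.471,0.176,0.118,0.200,0.533,0.133,0.133,0.200,0.600,0.000,0.200
MH,MH,0.167,0.333,0.167,0.333,0.000,0.115,0.692,0.192,0.500,0.000,0.000,0.500
MH,H,0.000,0.222,0.111,0.667,0.061,0.091,0.182,0.667,0.000,0.500,0.000,0.500
H,L,0.556,0.222,0.222,0.000,0.429,0.500,0.071,0.000,0.500,0.500,0.000,0.000
H,ML,0.250,0.688,0.063,0.000,0.267,0.333,0.267,0.133,0.375,0.500,0.125,0.000
H,MH,0.143,0.286,0.286,0.286,0.143,0.357,0.357,0.143,0.000,0.000,0.250,0.750
H,H,0.000,0.000,0.200,0.800,0.222,0.000,0.111,0.667,0.000,0.182,0.182,0.636
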