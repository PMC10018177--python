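DMU,TEC,TC,PTEC,SEC,TFPC
Beijing,1,1,1,1,1
Tianjin,1,0.974,1,1,0.974
Hebei,1.015,0.963,1.012,1.003,0.977
Shanxi,1.007,0.945,1.011,0.996,0.952
Inner Mongolia,1.03,0.982,1.03,1,1.011
Liaoning,1.043,0.936,1.036,1.007,0.976
Jilin,1,0.977,1,1,0.977
Heilongjiang,0.985,0.948,0.987,0.998,0.934
Shanghai,1,1.036,1,1,1.036
Jiangsu,0.991,0.973,1,0.991,0.964
Zhejiang,1,0.981,1,1,0.981
Anhui,1.004,0.935,1.004,1,0.939
Fujian,1.083,0.942,1.081,1.002,1.02
Jiangxi,1,0.973,1,1,0.973
Shandong,0.989,0.908,1,0.989,0.898
Henan,1,0.991,1,1,0.991
Hubei,1,0.874,1,1,0.874
Hunan,1.006,0.959,1.003,1.003,0.965
Guangdong,0.992,0.974,1,0.992,0.966
Guangxi,0.989,1.002,0.986,1.003,0.99
Hainan,1,1.003,1,1,1.003
Chongqing,1.01,0.955,1.01,1.001,0.964
Sichuan,1,0.895,1,1,0.895
Guizhou,0.97,0.869,0.972,0.998,0.843
Yunnan,0.972,0.953,0.974,0.998,0.927
Tibet,1.008,1.140,1,1.008,1.149
Shaanxi,1,0.939,1,1,0.939
Gansu,1.034,0.966,1.031,1.002,0.999
Qinghai,1,0.903,1,1,0.903
Ningxia,1,0.873,1,1,0.873
Xinjiang,1.028,0.922,1.023,1.004,0.948
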