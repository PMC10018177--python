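DMU,TE,PTE,SE,RTS,SBM,Rank
Beijing,1,1,1,CRS,2.075259,3
Tianjin,1,1,1,CRS,1.113012,9
Hebei,0.923478,0.941243,0.981125,CRS,0.660007,27
Shanxi,0.663327,0.804785,0.824229,CRS,0.537396,30
Inner Mongolia,0.88907,0.905911,0.98141,CRS,0.767648,23
Liaoning,1,1,1,CRS,1.065222,13
Jilin,1,1,1,CRS,1.151649,7
Heilongjiang,0.806433,0.913878,0.88243,DRS,0.742034,24
Shanghai,1,1,1,CRS,2.765687,2
Jiangsu,0.863247,1,0.863247,DRS,1,17
Zhejiang,1,1,1,CRS,1.093885,10
Anhui,0.988325,0.989857,0.998452,CRS,0.928381,22
Fujian,0.920666,0.921996,0.998557,CRS,0.697082,26
Jiangxi,1,1,1,CRS,1.801637,4
Shandong,0.910557,1,0.910557,DRS,1,18
Henan,1,1,1,CRS,1,19
Hubei,1,1,1,CRS,1.148148,8
Hunan,1,1,1,CRS,1.081579,11
Guangdong,0.939754,1,0.939754,DRS,1,20
Guangxi,0.848276,0.849864,0.998132,CRS,0.524982,31
Hainan,1,1,1,CRS,1.552696,5
Chongqing,0.862676,1,0.862676,DRS,1.010352,16
Sichuan,1,1,1,CRS,1,21
Guizhou,0.736317,0.820939,0.896921,CRS,0.605067,28
Yunnan,0.80127,0.80203,0.999052,CRS,0.59572,29
Tibet,1,1,1,CRS,4.366281,1
Shaanxi,0.980765,1,0.980765,DRS,1.014799,14
Gansu,0.986527,0.986827,0.999696,CRS,0.717468,25
Qinghai,1,1,1,CRS,1.162113,6
Ningxia,1,1,1,CRS,1.066009,12
Xinjiang,1,1,1,CRS,1.014693,15
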