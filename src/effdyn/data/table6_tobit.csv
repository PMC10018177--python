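variable,group,coef,se,t,p,ci_low,ci_high
Constant,,0.9794,0.0456,21.4800,0.0000,0.8896,1.0692
Entitled group,Support subjects,0.1308,0.0559,2.3400,0.0200,0.0207,0.2409
Extreme poverty group,Support subjects,0.2251,0.0662,3.4000,0.0010,0.0946,0.3556
Self-paid group,Support subjects,0.0986,0.0646,1.5300,0.1280,-0.0287,0.2259
Annual older people,Support subjects,0.0949,0.0566,1.6800,0.0950,-0.0167,0.2064
Women,Human resources,0.3895,0.1276,3.0500,0.0030,0.1382,0.6409
Junior college,Human resources,-0.1312,0.1017,-1.2900,0.1980,-0.3315,0.0692
College graduate and above,Human resources,0.0895,0.0899,1.0000,0.3210,-0.0877,0.2666
Aged 35 and below,Human resources,-0.1508,0.1039,-1.4500,0.1480,-0.3556,0.0540
Aged between 35 to 45,Human resources,-0.3176,0.1314,-2.4200,0.0160,-0.5764,-0.0588
Aged between 46 to 55,Human resources,-0.0191,0.0878,-0.2200,0.8280,-0.1920,0.1538
Aged 56 and above,Human resources,0.1321,0.0825,1.6000,0.1110,-0.0305,0.2947
Social workers,Human resources,0.0321,0.0512,0.6300,0.5320,-0.0688,0.1330
The numbers of volunteers,Human resources,0.0275,0.1244,0.2200,0.8250,-0.2176,0.2726
Volunteer service hours,Human resources,0.1321,0.1423,0.9300,0.3540,-0.1482,0.4125
Construction space,Non-human resources,-0.2101,0.0716,-2.9300,0.0040,-0.3511,-0.0690
LR,,62.2000,,,,,
R2,,0.2400,,,,,
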