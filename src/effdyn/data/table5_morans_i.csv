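year,total_moran,total_p,human_moran,human_p,nonhuman_moran,nonhuman_p
2013,-0.123,0.167,-0.081,0.345,-0.141,0.099
2014,0.024,0.252,-0.059,0.471,0.081,0.079
2015,-0.162,0.108,-0.083,0.306,-0.179,0.072
2016,-0.046,0.498,-0.097,0.147,0.016,0.269
2017,-0.019,0.184,-0.006,0.074,-0.031,0.477
2018,0.031,0.239,0.110,0.113,0.016,0.202
2019,-0.024,0.384,-0.019,0.406,-0.018,0.369
2020,-0.040,0.449,-0.079,0.374,-0.012,0.314
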