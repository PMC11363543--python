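year,I,Z,p
2012,0.360,3.202,0.001
2013,0.376,3.345,0.001
2014,0.238,2.217,0.027
2015,0.258,2.377,0.018
2016,0.135,1.379,0.168
2017,0.126,1.298,0.194
2018,0.258,2.363,0.018
2019,0.241,2.220,0.026
2020,0.203,1.930,0.054
2021,0.186,1.789,0.074
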