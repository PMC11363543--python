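region,MI,EC,TC
Tianjin,1.000,1.009,0.992
Hebei,0.878,0.914,0.991
Shanxi,0.901,0.958,0.944
Inner Mongolia,0.926,0.985,0.944
Liaoning,0.920,0.969,0.950
Jilin,0.918,0.972,0.944
Heilongjiang,0.916,0.971,0.942
Jiangsu,1.015,1.004,1.010
Zhejiang,0.971,1.003,0.967
Anhui,0.953,0.961,0.994
Fujian,0.935,0.968,0.965
Jiangxi,0.934,0.962,0.988
Shandong,0.956,0.969,1.000
Henan,1.016,1.007,1.010
Hubei,0.984,0.998,0.984
Hunan,1.002,1.002,1.001
Guangdong,0.984,0.976,1.013
Guangxi,0.973,0.999,0.972
Hainan,0.857,0.892,0.964
Chongqing,0.992,1.031,0.963
Sichuan,0.974,0.991,0.982
Guizhou,0.934,0.942,0.995
Yunnan,0.985,1.000,0.985
Xizang,0.767,0.898,0.854
Shaanxi,0.945,0.982,0.962
Gansu,0.949,0.988,0.961
Qinghai,0.905,1.009,0.894
Ningxia,0.905,1.001,0.904
Xinjiang,0.937,0.955,0.988
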