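region,2012,2013,2014,2015,2016,2017,2018,2019,2020,2021
Tianjin,1.027,1.031,0.922,1.022,1.014,1.005,0.952,1.030,1.004,1.008
Hebei,1.010,0.936,0.804,0.779,0.886,0.588,0.548,0.463,0.365,0.286
Shanxi,0.363,0.345,0.320,0.305,0.302,0.331,0.305,0.268,0.196,0.130
Inner Mongolia,0.332,0.350,0.325,0.299,0.324,0.332,0.297,0.212,0.179,0.156
Liaoning,0.473,0.465,0.440,0.418,0.426,0.464,0.430,0.357,0.244,0.208
Jilin,0.308,0.233,0.220,0.198,0.203,0.241,0.255,0.186,0.119,0.121
Heilongjiang,0.489,0.531,0.463,0.486,0.514,0.520,0.375,0.329,0.216,0.197
Jiangsu,0.717,0.815,0.843,0.870,0.851,1.030,0.928,1.011,0.748,0.757
Zhejiang,1.016,0.941,1.011,1.013,0.932,1.010,1.011,1.031,0.664,0.708
Anhui,0.704,0.723,0.717,0.689,0.663,0.720,0.689,0.679,0.529,0.439
Fujian,0.714,0.665,0.600,0.565,0.546,0.520,0.516,0.524,0.385,0.375
Jiangxi,1.013,0.840,0.664,0.673,0.665,0.699,0.664,0.613,0.525,0.526
Shandong,1.004,0.630,0.624,0.600,0.640,0.662,0.654,0.593,0.537,0.605
Henan,0.902,0.875,0.916,0.962,1.017,1.006,1.032,1.022,0.900,1.023
Hubei,0.831,0.850,0.813,0.824,0.900,1.021,1.003,1.012,0.666,0.660
Hunan,0.718,0.749,0.681,0.672,0.763,0.844,1.031,1.064,0.742,0.661
Guangdong,0.671,0.715,0.690,0.664,0.653,0.619,0.617,0.628,0.523,0.567
Guangxi,0.895,1.109,0.897,0.832,0.792,0.741,0.689,0.732,0.660,0.663
Hainan,0.883,1.007,0.909,0.809,0.735,0.686,0.550,0.466,0.178,0.161
Chongqing,1.022,1.011,0.923,0.881,0.891,1.009,0.940,1.032,0.885,0.917
Sichuan,1.052,0.955,0.896,0.872,0.918,1.047,0.950,1.046,0.801,0.786
Guizhou,1.101,1.005,0.762,0.614,0.552,0.582,0.632,0.648,0.512,0.550
Yunnan,1.016,1.029,1.011,1.011,1.015,1.015,0.982,1.013,0.842,0.872
Xizang,1.217,1.041,0.685,1.008,0.618,0.519,0.392,0.221,0.126,0.072
Shaanxi,0.423,0.407,0.401,0.420,0.392,0.432,0.426,0.379,0.240,0.232
Gansu,0.547,0.521,0.452,0.451,0.483,0.502,0.475,0.438,0.377,0.333
Qinghai,1.056,0.927,1.019,0.738,0.824,0.716,0.602,0.550,0.459,0.397
Ningxia,1.046,1.007,1.021,1.006,1.009,1.007,0.692,0.615,0.418,0.387
Xinjiang,0.749,0.865,0.927,1.008,1.005,0.949,0.765,0.822,0.544,0.344
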