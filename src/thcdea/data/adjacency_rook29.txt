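# First-order rook contiguity between the 29 study provinces.
# One undirected edge per line; Hainan is linked to Guangdong so that no
# province is isolated. Beijing and Shanghai are not part of the study set.
Tianjin,Hebei
Hebei,Shanxi
Hebei,Inner Mongolia
Hebei,Liaoning
Hebei,Shandong
Hebei,Henan
Shanxi,Inner Mongolia
Shanxi,Shaanxi
Shanxi,Henan
Inner Mongolia,Liaoning
Inner Mongolia,Jilin
Inner Mongolia,Heilongjiang
Inner Mongolia,Shaanxi
Inner Mongolia,Ningxia
Inner Mongolia,Gansu
Liaoning,Jilin
Jilin,Heilongjiang
Jiangsu,Shandong
Jiangsu,Anhui
Jiangsu,Zhejiang
Zhejiang,Anhui
Zhejiang,Jiangxi
Zhejiang,Fujian
Anhui,Jiangxi
Anhui,Hubei
Anhui,Henan
Anhui,Shandong
Fujian,Jiangxi
Fujian,Guangdong
Jiangxi,Hubei
Jiangxi,Hunan
Jiangxi,Guangdong
Shandong,Henan
Henan,Shaanxi
Henan,Hubei
Hubei,Shaanxi
Hubei,Chongqing
Hubei,Hunan
Hunan,Chongqing
Hunan,Guizhou
Hunan,Guangxi
Hunan,Guangdong
Guangdong,Guangxi
Guangdong,Hainan
Guangxi,Guizhou
Guangxi,Yunnan
Chongqing,Sichuan
Chongqing,Shaanxi
Chongqing,Guizhou
Sichuan,Qinghai
Sichuan,Gansu
Sichuan,Shaanxi
Sichuan,Guizhou
Sichuan,Yunnan
Sichuan,Xizang
Guizhou,Yunnan
Yunnan,Xizang
Xizang,Xinjiang
Xizang,Qinghai
Shaanxi,Gansu
Shaanxi,Ningxia
Gansu,Xinjiang
Gansu,Qinghai
Gansu,Ningxia
Qinghai,Xinjiang
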