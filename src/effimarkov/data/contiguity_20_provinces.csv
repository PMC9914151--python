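unit_a,unit_b
Anhui,Henan
Anhui,Hubei
Anhui,Jiangxi
Chongqing,Guizhou
Chongqing,Hubei
Chongqing,Hunan
Chongqing,Shaanxi
Chongqing,Sichuan
Gansu,Inner Mongolia
Gansu,Ningxia
Gansu,Qinghai
Gansu,Shaanxi
Gansu,Sichuan
Gansu,Xinjiang
Guangxi,Guizhou
Guangxi,Hunan
Guangxi,Yunnan
Guizhou,Hunan
Guizhou,Sichuan
Guizhou,Yunnan
Heilongjiang,Inner Mongolia
Heilongjiang,Jilin
Henan,Hubei
Henan,Shaanxi
Henan,Shanxi
Hubei,Hunan
Hubei,Jiangxi
Hubei,Shaanxi
Hunan,Jiangxi
Inner Mongolia,Jilin
Inner Mongolia,Ningxia
Inner Mongolia,Shaanxi
Inner Mongolia,Shanxi
Ningxia,Shaanxi
Qinghai,Sichuan
Qinghai,Tibet
Qinghai,Xinjiang
Shaanxi,Shanxi
Shaanxi,Sichuan
Sichuan,Tibet
Sichuan,Yunnan
Tibet,Xinjiang
Tibet,Yunnan
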