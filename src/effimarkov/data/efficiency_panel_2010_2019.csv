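unit,year,region,rho
Anhui,2010,central,1.101
Anhui,2011,central,1.076
Anhui,2012,central,1.075
Anhui,2013,central,1.087
Anhui,2014,central,1.068
Anhui,2015,central,1.063
Anhui,2016,central,1.051
Anhui,2017,central,1.340
Anhui,2018,central,1.318
Anhui,2019,central,1.485
Chongqing,2010,western,1.047
Chongqing,2011,western,1.076
Chongqing,2012,western,1.086
Chongqing,2013,western,1.052
Chongqing,2014,western,1.088
Chongqing,2015,western,1.082
Chongqing,2016,western,1.090
Chongqing,2017,western,1.098
Chongqing,2018,western,1.081
Chongqing,2019,western,1.082
Gansu,2010,western,1.006
Gansu,2011,western,0.676
Gansu,2012,western,0.558
Gansu,2013,western,0.650
Gansu,2014,western,0.585
Gansu,2015,western,0.559
Gansu,2016,western,0.565
Gansu,2017,western,0.467
Gansu,2018,western,0.527
Gansu,2019,western,0.442
Guangxi,2010,western,1.057
Guangxi,2011,western,1.014
Guangxi,2012,western,1.037
Guangxi,2013,western,1.092
Guangxi,2014,western,1.069
Guangxi,2015,western,1.049
Guangxi,2016,western,1.035
Guangxi,2017,western,0.871
Guangxi,2018,western,1.001
Guangxi,2019,western,1.025
Guizhou,2010,western,1.101
Guizhou,2011,western,1.093
Guizhou,2012,western,1.081
Guizhou,2013,western,1.056
Guizhou,2014,western,0.508
Guizhou,2015,western,0.292
Guizhou,2016,western,0.319
Guizhou,2017,western,0.361
Guizhou,2018,western,0.422
Guizhou,2019,western,0.446
Heilongjiang,2010,central,1.015
Heilongjiang,2011,central,0.634
Heilongjiang,2012,central,0.528
Heilongjiang,2013,central,0.583
Heilongjiang,2014,central,0.573
Heilongjiang,2015,central,0.589
Heilongjiang,2016,central,0.565
Heilongjiang,2017,central,0.393
Heilongjiang,2018,central,0.364
Heilongjiang,2019,central,0.277
Henan,2010,central,1.222
Henan,2011,central,1.227
Henan,2012,central,1.105
Henan,2013,central,1.112
Henan,2014,central,1.124
Henan,2015,central,1.124
Henan,2016,central,1.132
Henan,2017,central,1.122
Henan,2018,central,1.090
Henan,2019,central,1.074
Hubei,2010,central,1.158
Hubei,2011,central,1.209
Hubei,2012,central,1.299
Hubei,2013,central,1.273
Hubei,2014,central,1.312
Hubei,2015,central,1.316
Hubei,2016,central,1.310
Hubei,2017,central,1.081
Hubei,2018,central,1.091
Hubei,2019,central,1.087
Hunan,2010,central,0.756
Hunan,2011,central,1.011
Hunan,2012,central,0.797
Hunan,2013,central,0.793
Hunan,2014,central,1.023
Hunan,2015,central,1.041
Hunan,2016,central,1.040
Hunan,2017,central,1.020
Hunan,2018,central,1.062
Hunan,2019,central,1.038
Inner Mongolia,2010,western,0.647
Inner Mongolia,2011,western,0.599
Inner Mongolia,2012,western,0.509
Inner Mongolia,2013,western,0.528
Inner Mongolia,2014,western,0.499
Inner Mongolia,2015,western,0.508
Inner Mongolia,2016,western,0.524
Inner Mongolia,2017,western,0.475
Inner Mongolia,2018,western,0.475
Inner Mongolia,2019,western,0.297
Jiangxi,2010,central,1.025
Jiangxi,2011,central,1.080
Jiangxi,2012,central,1.002
Jiangxi,2013,central,1.001
Jiangxi,2014,central,1.028
Jiangxi,2015,central,1.043
Jiangxi,2016,central,1.059
Jiangxi,2017,central,1.054
Jiangxi,2018,central,1.052
Jiangxi,2019,central,1.026
Jilin,2010,central,0.516
Jilin,2011,central,0.405
Jilin,2012,central,0.420
Jilin,2013,central,0.369
Jilin,2014,central,0.381
Jilin,2015,central,0.323
Jilin,2016,central,0.351
Jilin,2017,central,0.426
Jilin,2018,central,0.466
Jilin,2019,central,0.366
Ningxia,2010,western,1.425
Ningxia,2011,western,1.547
Ningxia,2012,western,1.538
Ningxia,2013,western,1.608
Ningxia,2014,western,1.651
Ningxia,2015,western,1.634
Ningxia,2016,western,1.586
Ningxia,2017,western,1.562
Ningxia,2018,western,1.492
Ningxia,2019,western,1.497
Qinghai,2010,western,1.266
Qinghai,2011,western,1.253
Qinghai,2012,western,1.210
Qinghai,2013,western,1.222
Qinghai,2014,western,1.155
Qinghai,2015,western,1.109
Qinghai,2016,western,1.110
Qinghai,2017,western,1.072
Qinghai,2018,western,1.023
Qinghai,2019,western,1.011
Shaanxi,2010,western,0.428
Shaanxi,2011,western,0.303
Shaanxi,2012,western,0.315
Shaanxi,2013,western,0.343
Shaanxi,2014,western,0.307
Shaanxi,2015,western,0.336
Shaanxi,2016,western,0.348
Shaanxi,2017,western,0.255
Shaanxi,2018,western,0.270
Shaanxi,2019,western,0.132
Shanxi,2010,central,0.514
Shanxi,2011,central,0.502
Shanxi,2012,central,0.468
Shanxi,2013,central,0.459
Shanxi,2014,central,0.443
Shanxi,2015,central,0.410
Shanxi,2016,central,0.413
Shanxi,2017,central,0.416
Shanxi,2018,central,0.451
Shanxi,2019,central,0.302
Sichuan,2010,western,1.138
Sichuan,2011,western,1.122
Sichuan,2012,western,1.144
Sichuan,2013,western,1.148
Sichuan,2014,western,1.156
Sichuan,2015,western,1.126
Sichuan,2016,western,1.136
Sichuan,2017,western,1.312
Sichuan,2018,western,1.439
Sichuan,2019,western,1.460
Tibet,2010,western,1.127
Tibet,2011,western,0.412
Tibet,2012,western,1.032
Tibet,2013,western,0.430
Tibet,2014,western,0.390
Tibet,2015,western,0.446
Tibet,2016,western,0.468
Tibet,2017,western,1.003
Tibet,2018,western,1.342
Tibet,2019,western,1.252
Xinjiang,2010,western,0.779
Xinjiang,2011,western,0.683
Xinjiang,2012,western,0.624
Xinjiang,2013,western,0.539
Xinjiang,2014,western,0.640
Xinjiang,2015,western,1.001
Xinjiang,2016,western,0.815
Xinjiang,2017,western,0.756
Xinjiang,2018,western,0.733
Xinjiang,2019,western,0.670
Yunnan,2010,western,1.065
Yunnan,2011,western,1.044
Yunnan,2012,western,1.042
Yunnan,2013,western,1.025
Yunnan,2014,western,1.011
Yunnan,2015,western,1.018
Yunnan,2016,western,1.019
Yunnan,2017,western,0.475
Yunnan,2018,western,0.658
Yunnan,2019,western,1.004
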