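organ,cell_line,pulse_duration_us,e0,k1,r2_e,a0,k2,r2_a,ec100
esophagus,KYSE-150,25,2756.213,0.010,0.885,681.381,0.005,0.628,1013.954
esophagus,KYSE-150,50,2714.890,0.013,0.950,1088.084,0.016,0.863,739.894
esophagus,KYSE-150,75,2059.141,0.014,0.963,644.249,0.014,0.926,507.778
esophagus,KYSE-150,100,1862.259,0.014,0.961,634.689,0.015,0.995,459.227
esophagus,KYSE-410,25,2173.894,0.009,0.922,333.371,0.003,0.215,883.839
esophagus,KYSE-410,50,2001.763,0.010,0.915,362.119,0.013,0.957,736.407
esophagus,KYSE-410,75,1785.091,0.010,0.997,176.637,0.000,0.024,656.698
esophagus,KYSE-410,100,1524.046,0.008,0.968,372.925,0.003,0.258,684.798
stomach,GES-1,25,3690.107,0.010,0.955,646.374,-0.001,0.182,1357.515
stomach,GES-1,50,3444.518,0.015,0.944,959.728,0.010,0.871,768.576
stomach,GES-1,75,3510.741,0.018,0.920,1210.089,0.022,0.837,580.322
stomach,GES-1,100,3244.770,0.018,0.894,1533.835,0.028,0.823,536.357
stomach,MGC-823,25,4539.967,0.016,0.939,980.346,0.007,0.766,916.604
stomach,MGC-823,50,3546.443,0.015,0.939,1172.765,0.013,0.942,791.318
stomach,MGC-823,75,3651.689,0.020,0.966,1268.881,0.017,0.963,494.202
stomach,MGC-823,100,5669.169,0.042,0.945,3843.981,0.071,0.978,85.012
stomach,MKN-45,25,3082.787,0.010,0.961,963.341,0.011,0.893,1134.094
stomach,MKN-45,50,2492.628,0.010,0.932,1011.575,0.018,0.951,916.987
stomach,MKN-45,75,2171.824,0.013,0.996,723.632,0.014,0.989,591.891
stomach,MKN-45,100,1605.015,0.011,0.982,582.408,0.011,0.962,534.263
stomach,SGC-7901,25,3686.389,0.016,0.975,960.052,0.016,0.938,744.269
stomach,SGC-7901,50,2990.836,0.015,0.944,832.338,0.014,0.915,667.346
stomach,SGC-7901,75,3271.241,0.025,0.954,993.818,0.025,0.937,268.520
stomach,SGC-7901,100,3407.636,0.029,0.915,1355.732,0.042,0.905,187.499
colon,SW-620,25,2386.836,0.008,0.942,740.177,0.009,0.949,1072.475
colon,SW-620,50,2243.286,0.009,0.908,720.728,0.004,0.569,912.052
colon,SW-620,75,2140.876,0.010,0.936,806.931,0.005,0.897,787.584
colon,SW-620,100,2116.665,0.019,0.800,1354.309,0.028,0.882,316.587
colon,SW-480,25,2296.339,0.010,0.995,569.940,0.005,0.660,844.776
colon,SW-480,50,2161.404,0.010,0.967,890.061,0.008,0.877,795.136
colon,SW-480,75,1677.443,0.012,0.891,523.802,0.007,0.985,505.236
colon,SW-480,100,1542.091,0.013,0.915,377.732,0.018,0.884,420.269
colon,HCT-116,25,2699.715,0.010,0.927,264.336,-0.004,0.401,993.170
colon,HCT-116,50,3305.015,0.018,0.964,546.569,0.002,0.224,546.315
colon,HCT-116,75,2560.682,0.016,0.944,319.794,-0.007,0.924,516.993
colon,HCT-116,100,2556.739,0.020,0.990,503.801,-0.001,0.228,346.017
colon,LoVo,25,2678.650,0.009,0.964,491.367,0.009,0.977,1089.058
colon,LoVo,50,2481.962,0.009,0.930,720.808,0.014,0.925,1009.090
colon,LoVo,75,2417.015,0.012,0.905,645.304,0.017,0.783,727.991
colon,LoVo,100,2100.307,0.012,0.901,675.382,0.012,0.805,632.600
liver,L-02,25,2193.061,0.007,0.980,375.922,0.001,0.092,1089.042
liver,L-02,50,1539.792,0.007,0.956,430.113,0.006,0.940,764.638
liver,L-02,75,1271.158,0.007,0.878,468.985,0.019,0.916,631.238
liver,L-02,100,1332.386,0.012,0.972,379.581,0.014,0.911,401.307
liver,Hep-3B,25,2139.251,0.011,0.946,343.131,0.002,0.354,712.095
liver,Hep-3B,50,1576.574,0.009,0.921,426.943,0.010,0.938,640.987
liver,Hep-3B,75,1430.396,0.008,0.854,428.361,0.014,0.891,642.718
liver,Hep-3B,100,1165.961,0.007,0.871,463.969,0.017,0.919,578.999
liver,Hep-G2,25,1814.403,0.009,0.949,435.577,-0.003,0.609,737.681
liver,Hep-G2,50,1691.575,0.010,0.922,533.418,0.010,0.957,622.296
liver,Hep-G2,75,1441.026,0.009,0.902,538.309,0.020,0.928,585.877
liver,Hep-G2,100,1048.643,0.008,0.869,1057.822,0.029,0.956,471.186
liver,Huh-7,25,2813.031,0.010,0.919,495.029,0.004,0.898,1034.856
liver,Huh-7,50,1957.116,0.008,0.903,365.556,-0.002,0.680,879.389
liver,Huh-7,75,1581.337,0.007,0.933,452.905,0.004,0.618,785.269
liver,Huh-7,100,1213.478,0.006,0.807,418.125,0.015,0.945,665.971
bile_duct,HCCC-9810,25,1719.363,0.007,0.870,322.897,0.003,0.268,853.810
bile_duct,HCCC-9810,50,1691.929,0.010,0.920,358.120,0.003,0.419,622.426
bile_duct,HCCC-9810,75,1611.441,0.015,0.921,563.781,0.005,0.774,359.561
bile_duct,HCCC-9810,100,1466.889,0.016,0.931,697.996,0.012,0.887,296.160
bile_duct,HIBEpiC,25,2883.189,0.010,0.955,570.890,-0.004,0.906,1060.666
bile_duct,HIBEpiC,50,3153.721,0.013,0.994,695.075,-0.002,0.564,859.489
bile_duct,HIBEpiC,75,2003.759,0.011,0.980,482.750,-0.005,0.730,666.993
bile_duct,HIBEpiC,100,1866.801,0.019,0.979,629.820,0.005,0.469,279.215
bile_duct,HuCCT-1,25,2592.384,0.011,0.982,775.667,0.006,0.953,862.930
bile_duct,HuCCT-1,50,2403.929,0.012,0.959,784.966,0.007,0.998,724.050
bile_duct,HuCCT-1,75,2292.476,0.013,0.968,853.363,0.008,0.800,624.773
bile_duct,HuCCT-1,100,2175.557,0.015,0.945,845.391,0.011,0.891,485.432
bile_duct,QBC-939,25,3297.848,0.012,0.987,1118.228,-0.001,0.178,993.293
bile_duct,QBC-939,50,2671.958,0.018,0.945,893.800,0.008,0.882,441.672
bile_duct,QBC-939,75,2157.099,0.018,0.979,923.800,0.007,0.786,356.566
bile_duct,QBC-939,100,1923.263,0.024,0.963,967.059,0.008,0.716,174.474
pancreas,MIA PaCa-2,25,2189.830,0.005,0.882,656.004,0.001,0.138,1328.199
pancreas,MIA PaCa-2,50,1735.254,0.007,0.848,538.921,0.005,0.695,861.702
pancreas,MIA PaCa-2,75,1488.322,0.007,0.759,528.346,0.009,0.839,739.079
pancreas,MIA PaCa-2,100,1300.553,0.006,0.848,569.525,0.012,0.888,713.759
pancreas,PANC-1,25,,,,,,,
pancreas,PANC-1,50,1943.466,0.010,0.985,628.851,0.008,0.985,714.961
pancreas,PANC-1,75,1658.539,0.010,0.940,698.783,0.013,0.960,610.142
pancreas,PANC-1,100,1599.016,0.011,0.913,422.316,0.006,0.839,532.266
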