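wavelength_nm,mua_water_cm1,mua_fat_cm1,eps_hbo2_M1cm1,eps_hhb_M1cm1,eps_oxcco_M1cm1,eps_redcco_M1cm1,eps_diffcco_M1cm1
780,0.01142,0.00409,735.8251,1104.715,3755.500,1794.484,2049.479
781,0.01127,0.00391,741.9921,1080.047,3764.925,1790.206,2060.684
782,0.01118,0.00378,748.2894,1056.812,3773.988,1786.436,2071.889
783,0.01117,0.00366,754.7170,1036.922,3784.138,1781.724,2084.570
784,0.01099,0.00360,761.1011,1017.031,3791.388,1776.323,2097.382
785,0.01087,0.00357,767.9195,997.2270,3798.275,1770.849,2107.544
786,0.01072,0.00355,774.0865,981.9398,3805.525,1764.759,2117.750
787,0.01055,0.00353,780.6009,966.5658,3814.588,1760.083,2126.566
788,0.01061,0.00349,787.2022,951.2786,3822.200,1754.065,2135.469
789,0.01053,0.00346,793.8903,938.2498,3827.638,1748.591,2142.766
790,0.01036,0.00346,800.3179,926.1764,3835.250,1742.864,2150.062
791,0.01024,0.00347,806.7889,914.0596,3842.500,1737.716,2156.663
792,0.01022,0.00347,813.1730,903.1588,3850.475,1732.243,2163.264
793,0.01012,0.00347,819.4703,893.6912,3855.913,1725.428,2175.729
794,0.01005,0.00352,826.2018,884.1801,3862.438,1720.570,2188.149
795,0.00983,0.00359,832.8031,874.9731,3867.513,1714.154,2200.961
796,0.00974,0.00369,838.9701,867.3729,3872.225,1708.136,2213.642
797,0.00969,0.00379,845.5714,859.7728,3878.025,1702.300,2227.323
798,0.00964,0.00387,852.1726,852.1726,3878.388,1693.818,2241.046
799,0.00951,0.00393,858.6002,845.8754,3887.088,1691.751,2251.209
800,0.00956,0.00403,865.0712,839.6650,3891.075,1685.843,2261.328
801,0.00951,0.00413,871.3685,833.5848,3897.963,1680.333,2266.018
802,0.00936,0.00424,877.7960,828.2864,3900.138,1674.968,2270.709
803,0.00939,0.00434,884.2670,823.5092,3903.038,1669.276,2275.616
804,0.00935,0.00442,890.6946,818.7754,3907.750,1666.703,2280.611
805,0.00932,0.00454,897.0787,814.3890,3912.825,1661.011,2286.430
806,0.00928,0.00467,903.5497,810.9147,3915.363,1655.973,2292.119
807,0.00923,0.00482,909.9772,807.3100,3919.350,1651.224,2298.504
808,0.00929,0.00497,916.1876,803.7922,3920.438,1647.273,2304.931
809,0.00938,0.00511,922.4849,801.1865,3925.513,1643.684,2310.794
810,0.00942,0.00527,928.8690,798.4938,3930.588,1642.451,2316.614
811,0.00952,0.00547,935.1663,795.8881,3933.488,1639.080,2320.609
812,0.00958,0.00567,941.3767,793.8903,3935.300,1636.978,2324.692
813,0.00969,0.00583,947.5437,791.9794,3937.475,1632.736,2327.514
814,0.00964,0.00594,953.6673,790.1988,3937.475,1628.966,2330.294
815,0.00984,0.00603,960.0514,788.5919,3940.375,1625.704,2332.900
816,0.00995,0.00615,966.3487,787.2022,3942.550,1623.746,2335.505
817,0.01011,0.00633,972.5591,785.8993,3943.275,1619.831,2338.198
818,0.01021,0.00654,978.6392,784.6833,3944.000,1616.025,2340.891
819,0.01019,0.00674,984.5456,783.9884,3944.363,1612.038,2343.583
820,0.01047,0.00691,990.8429,783.2067,3944.725,1609.138,2346.319
821,0.01056,0.00708,997.0533,782.5118,3944.363,1604.969,2347.188
822,0.01060,0.00724,1002.960,781.9906,3942.550,1602.359,2348.013
823,0.01093,0.00740,1008.823,781.5129,3939.288,1597.393,2346.493
824,0.01123,0.00758,1015.033,780.9918,3940.013,1596.196,2344.886
825,0.01144,0.00775,1020.853,780.6878,3939.650,1594.819,2342.324
826,0.01218,0.00786,1027.020,780.6009,3938.925,1592.861,2339.718
827,0.01260,0.00796,1033.056,780.3838,3937.113,1590.106,2336.287
828,0.01333,0.00799,1039.050,780.2969,3935.300,1587.786,2332.900
829,0.01384,0.00802,1044.652,780.2100,3933.850,1585.611,2329.425
830,0.01459,0.00803,1050.428,780.2100,3932.038,1585.575,2325.908
831,0.01510,0.00803,1056.117,780.2100,3929.500,1583.074,2322.694
832,0.01586,0.00801,1061.850,780.2100,3927.325,1583.545,2319.393
833,0.01638,0.00794,1067.713,780.2100,3924.425,1579.521,2316.831
834,0.01656,0.00785,1073.619,780.2969,3922.975,1579.920,2314.225
835,0.01699,0.00775,1079.439,780.2969,3921.888,1580.645,2312.531
836,0.01740,0.00764,1084.824,780.3838,3921.525,1581.479,2310.707
837,0.01740,0.00757,1090.427,780.5140,3919.713,1579.739,2310.012
838,0.01758,0.00751,1095.942,780.6878,3913.188,1577.854,2309.231
839,0.01773,0.00739,1101.501,780.9918,3906.663,1576.948,2308.406
840,0.01795,0.00726,1106.930,781.2958,3902.313,1575.389,2307.493
841,0.01813,0.00715,1112.532,781.5129,3899.050,1575.933,2305.626
842,0.01805,0.00703,1117.917,781.8169,3894.700,1575.860,2303.715
843,0.01814,0.00692,1122.999,782.1209,3889.263,1572.271,2301.327
844,0.01822,0.00685,1128.297,782.5118,3887.088,1574.193,2298.894
845,0.01835,0.00678,1133.595,783.1198,3882.738,1572.380,2296.636
846,0.01848,0.00669,1138.807,783.6844,3874.038,1569.951,2294.204
847,0.01856,0.00661,1143.888,784.2924,3868.238,1569.988,2292.814
848,0.01883,0.00651,1149.100,784.8136,3864.975,1571.764,2291.338
849,0.01898,0.00643,1154.398,785.4216,3860.988,1571.619,2290.599
850,0.01913,0.00637,1159.306,785.8993,3854.825,1573.939,2289.905
851,0.01908,0.00633,1164.213,786.8982,3845.763,1569.734,2287.299
852,0.01936,0.00632,1169.121,787.8102,3837.425,1571.764,2284.736
853,0.01931,0.00631,1173.898,788.8091,3830.175,1571.365,2279.916
854,0.01930,0.00633,1178.719,789.8948,3825.463,1572.525,2275.139
855,0.01934,0.00639,1183.887,790.9805,3817.850,1568.646,2267.929
856,0.01959,0.00647,1188.186,792.1097,3809.875,1568.864,2260.720
857,0.01960,0.00656,1193.094,793.2823,3802.988,1568.755,2252.121
858,0.01969,0.00662,1197.697,794.7155,3796.825,1569.843,2243.609
859,0.01972,0.00666,1202.301,796.1052,3787.763,1565.529,2236.747
860,0.01981,0.00674,1206.774,797.4950,3777.613,1563.064,2229.755
861,0.02001,0.00680,1211.074,799.1018,3768.550,1564.478,2225.325
862,0.02002,0.00690,1215.286,800.7087,3760.575,1561.868,2220.852
863,0.02008,0.00705,1219.673,802.3156,3751.513,1558.496,2216.422
864,0.01996,0.00724,1224.189,804.1831,3743.538,1554.146,2212.122
865,0.02034,0.00751,1228.272,806.0940,3736.288,1555.705,2206.346
866,0.02021,0.00786,1232.180,808.0049,3732.300,1561.106,2200.440
867,0.02045,0.00822,1236.393,810.0026,3723.238,1559.765,2193.535
868,0.02044,0.00860,1240.388,812.0004,3711.275,1560.708,2186.629
869,0.02085,0.00899,1244.601,814.0850,3698.950,1559.185,2176.727
870,0.02108,0.00938,1248.683,816.3868,3688.438,1559.584,2166.869
871,0.02116,0.00979,1252.592,818.6885,3679.013,1557.264,2152.364
872,0.02111,0.01022,1256.197,821.0771,3671.038,1554.509,2137.858
873,0.02138,0.01074,1259.801,823.5092,3661.975,1557.373,2125.046
874,0.02160,0.01133,1263.797,825.8978,3654.000,1557.771,2112.278
875,0.02172,0.01198,1267.488,828.2864,3643.488,1557.046,2102.376
876,0.02174,0.01264,1270.659,830.8053,3633.338,1558.315,2092.474
877,0.02217,0.01345,1274.263,833.3677,3621.846,1557.554,2084.049
878,0.02236,0.01430,1277.781,835.8866,3611.733,1559.983,2075.754
879,0.02278,0.01527,1281.082,838.4924,3599.480,1558.931,2067.893
880,0.02282,0.01636,1284.252,840.9678,3588.823,1560.744,2060.076
881,0.02290,0.01752,1287.466,843.5736,3577.005,1561.179,2052.476
882,0.02355,0.01867,1290.376,846.0925,3571.713,1564.043,2044.876
883,0.02366,0.01992,1293.459,848.6983,3560.874,1563.861,2035.365
884,0.02413,0.02121,1296.760,851.3909,3548.839,1564.260,2025.984
885,0.02421,0.02262,1299.670,853.9967,3538.508,1562.774,2015.908
886,0.02437,0.02414,1302.362,856.6024,3526.038,1561.251,2005.789
887,0.02440,0.02581,1305.489,859.1648,3512.879,1562.375,1995.409
888,0.02447,0.02754,1308.052,861.7705,3501.678,1562.085,1984.986
889,0.02504,0.02932,1310.484,864.2895,3489.461,1561.686,1972.001
890,0.02592,0.03116,1313.350,866.7649,3477.173,1564.985,1958.885
891,0.02579,0.03305,1316.173,869.1970,3466.080,1565.529,1946.204
892,0.02573,0.03491,1318.561,871.5856,3456.148,1567.378,1933.523
893,0.02612,0.03674,1320.646,873.9742,3441.575,1566.834,1919.799
894,0.02602,0.03833,1323.165,876.2760,3433.346,1569.154,1906.119
895,0.02643,0.03983,1325.858,878.4909,3423.595,1566.943,1891.135
896,0.0263,0.04121,1327.942,880.4886,3409.603,1567.378,1876.109
897,0.02667,0.04256,1330.070,882.4864,3398.764,1569.371,1861.430
898,0.0274,0.04384,1331.981,884.3539,3386.403,1569.118,1846.750
899,0.02781,0.04506,1333.762,886.0910,3373.099,1568.683,1833.852
900,0.02858,0.04633,1336.150,887.7848,3358.490,1570.386,1820.823
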