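participant_id,community,age_y,sex,body_mass_kg,TEE_kcal_day,FFM_kg,fat_pct,WT_L_day,steps,MVPA_min,ND_NO_ratio,kD_perday,kO_perday,ND_mol,NO_mol
D01,El Bokoch,38,F,48,2164,36.2,24.7,6.63,,,1.043,0.2269,0.2604,1539.2,1476.1
D02,El Bokoch,38,F,55,2536,37.3,32.7,6.66,,,1.033,0.2225,0.2593,1577.7,1526.7
D03,El Bokoch,23,F,50,2437,38.4,22.8,5.67,,,1.036,0.1839,0.2174,1625.4,1569.6
D04,El Bokoch,25,F,45,1717,29.8,33.7,6.97,,,1.046,0.2893,0.3240,1270.0,1214.1
D05,El Bokoch,22,F,39,1566,28.4,26.6,5.75,,,1.036,0.2515,0.2839,1203.6,1161.4
D06,El Bokoch,22,F,44,1797,32.7,26.0,6.57,,,1.033,0.2501,0.2823,1384.8,1340.3
D07,El Bokoch,54,M,52,2075,45.8,11.9,4.44,,,1.048,0.1197,0.1431,1953.6,1863.8
D08,El Bokoch,37,M,59,3235,50.6,14.8,9.15,,,1.028,0.2257,0.2609,2136.4,2079.0
D09,El Bokoch,32,M,50,2098,42.0,16.1,7.89,,,1.029,0.2344,0.2640,1772.2,1722.2
D10,El Bokoch,32,M,50,2521,40.4,19.3,6.70,,,1.018,0.2083,0.2422,1695.0,1665.3
D11,El Bokoch,34,M,44,1564,36.5,17.6,5.67,,,1.038,0.1930,0.2181,1548.8,1491.5
D12,El Bokoch,40,M,50,2444,38.8,21.7,7.63,,,1.037,0.2441,0.2795,1645.6,1587.6
D13,Illeret,31,F,57,2559,45.2,21.1,4.82,8483,61,1.028,0.1331,0.1619,1908.8,1856.9
D14,Illeret,26,F,65,2794,45.9,29.0,13.56,3931,18,1.032,0.3678,0.4067,1942.4,1882.9
D15,Illeret,30,F,46,2486,33.4,27.3,6.10,4409,17,1.041,0.2267,0.2663,1418.0,1361.8
D16,Illeret,39,F,57,2037,35.7,37.6,7.57,,,1.040,0.2633,0.2969,1514.9,1456.8
D17,Illeret,36,F,50,2476,38.7,22.2,11.65,,,1.035,0.3750,0.4155,1636.9,1582.0
D18,Illeret,35,F,52,1658,36.3,30.1,6.21,,,1.032,0.2134,0.2404,1534.1,1486.0
D19,Illeret,36,F,47,1715,29.8,36.6,6.91,,,1.050,0.2865,0.3212,1271.2,1210.1
D20,Illeret,35,M,56,3494,52.0,7.3,11.11,10845,56,1.036,0.2654,0.3034,2204.5,2128.3
D21,Illeret,45,M,49,3003,43.5,12.2,9.71,15776,33,1.035,0.2779,0.3172,1840.5,1777.6
D22,Illeret,50,M,45,1732,38.1,14.5,4.70,,,1.037,0.1532,0.1779,1616.9,1558.6
D23,Illeret,56,M,57,2242,41.7,26.8,4.92,,,1.027,0.1474,0.1755,1759.8,1714.1
D24,Illeret,22,M,55,2229,47.2,13.9,5.61,,,1.042,0.1475,0.1728,2004.8,1923.6
D25,Roto,20,F,46,2419,36.2,20.7,6.15,5905,32,1.028,0.2122,0.2481,1525.7,1484.8
D26,Roto,31,F,45,3320,40.7,10.2,8.92,3059,13,1.044,0.2715,0.3158,1730.5,1658.3
D27,Roto,28,F,49,2044,39.3,19.6,7.04,4790,13,1.054,0.2207,0.2507,1679.0,1593.6
D28,Roto,30,F,43,2541,36.1,15.8,6.48,,,1.063,0.2201,0.2579,1549.6,1458.0
D29,Roto,20,F,51,3392,43.3,14.9,7.36,,,1.060,0.2090,0.2497,1856.0,1751.3
D30,Roto,20,F,47,2514,37.0,21.7,6.82,,,1.041,0.2285,0.2655,1572.4,1510.2
D31,Roto,25,M,54,3441,51.3,4.5,9.10,8907,66,1.041,0.2201,0.2564,2177.1,2092.3
D32,Roto,34,M,55,3143,48.9,10.8,9.39,7538,21,1.041,0.2387,0.2741,2040.1,1987.9
D33,Roto,34,M,59,3041,51.7,12.5,8.57,,,1.040,0.2057,0.2380,2195.3,2111.2
D34,Roto,22,M,52,4172,47.7,7.8,7.83,,,1.041,0.2038,0.2482,2024.2,1944.0
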