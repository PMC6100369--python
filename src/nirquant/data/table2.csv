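id,peak_area,content_percent,origin
Sample 1,848.8,0.1885,Northeast of China
Sample 2,465.7,0.1283,Northeast of China
Sample 3,665.4,0.1613,Northeast of China
Sample 4,679.1,0.1634,Northeast of China
Sample 5,654.1,0.1595,Northeast of China
Sample 6,482.8,0.1313,Northeast of China
Sample 7,445.2,0.1247,Northeast of China
Sample 8,666.4,0.1615,Northeast of China
Sample 9,629.1,0.1556,Northeast of China
Sample 10,852.9,0.1891,Northeast of China
Sample 11,698.9,0.1665,Northeast of China
Sample 12,682.4,0.1639,Northeast of China
Sample 13,745.4,0.1735,Northeast of China
Sample 14,878.7,0.1928,Northeast of China
Sample 15,830.7,0.1859,Northeast of China
Sample 16,693.4,0.1656,Northeast of China
Sample 17,679.1,0.1634,Northeast of China
Sample 18,845.3,0.1880,Northeast of China
Sample 19,783.5,0.1791,Northeast of China
Sample 20,699.7,0.1666,Northeast of China
Sample 21,838.8,0.1871,Northeast of China
Sample 22,779.7,0.1785,Northeast of China
Sample 23,682.4,0.1639,Northeast of China
Sample 24,629.1,0.1556,Northeast of China
Sample 25,677.9,0.1632,Northeast of China
Sample 26,894.3,0.1949,Northeast of China
Sample 27,823.7,0.1849,Northeast of China
Sample 28,663.4,0.1610,Northeast of China
Sample 29,755.3,0.1749,Northeast of China
Sample 30,822.9,0.1848,Northeast of China
Sample 31,896.3,0.1952,"Anhui Bozhou, China"
Sample 32,921.5,0.1987,"Anhui Bozhou, China"
Sample 33,781.3,0.1788,"Anhui Bozhou, China"
Sample 34,2000.3,0.3265,"Anhui Bozhou, China"
Sample 35,1785.2,0.3035,"Anhui Bozhou, China"
Sample 36,931.2,0.2001,"Anhui Bozhou, China"
Sample 37,852.3,0.1890,"Anhui Bozhou, China"
Sample 38,763.2,0.1761,"Anhui Bozhou, China"
Sample 39,618.5,0.1539,"Anhui Bozhou, China"
Sample 40,1295.4,0.2472,"Anhui Bozhou, China"
Sample 41,1956.2,0.3219,"Anhui Bozhou, China"
Sample 42,1532.3,0.2752,"Anhui Bozhou, China"
Sample 43,765.4,0.1764,"Anhui Bozhou, China"
Sample 44,2150.5,0.3420,"Anhui Bozhou, China"
Sample 45,1005.6,0.2102,"Anhui Bozhou, China"
Sample 46,935.2,0.2006,"Anhui Bozhou, China"
Sample 47,1491.1,0.2705,"Anhui Bozhou, China"
Sample 48,1863.5,0.3120,"Anhui Bozhou, China"
Sample 49,1632.2,0.2866,"Anhui Bozhou, China"
Sample 50,653.2,0.1594,"Anhui Bozhou, China"
Sample 51,1238.5,0.2402,"Datong Shanxi, China"
Sample 52,1653.2,0.2890,"Datong Shanxi, China"
Sample 53,934.2,0.2005,"Datong Shanxi, China"
Sample 54,1456.3,0.2664,"Datong Shanxi, China"
Sample 55,1943.8,0.3206,"Datong Shanxi, China"
Sample 56,1523.2,0.2742,"Datong Shanxi, China"
Sample 57,1522.3,0.2741,"Datong Shanxi, China"
Sample 58,852.3,0.1890,"Datong Shanxi, China"
Sample 59,1456.2,0.2664,"Datong Shanxi, China"
Sample 60,1681.7,0.2922,"Datong Shanxi, China"
Sample 61,931.1,0.2000,"Datong Shanxi, China"
Sample 62,1079.9,0.2200,"Datong Shanxi, China"
Sample 63,1423.3,0.2625,"Datong Shanxi, China"
Sample 64,1266.7,0.2436,"Datong Shanxi, China"
Sample 65,1815.1,0.3068,"Datong Shanxi, China"
Sample 66,1756.3,0.3004,"Datong Shanxi, China"
Sample 67,1023.6,0.2126,"Datong Shanxi, China"
Sample 68,953.2,0.2031,"Datong Shanxi, China"
Sample 69,1563.2,0.2788,"Datong Shanxi, China"
Sample 70,1456.3,0.2664,"Datong Shanxi, China"
Sample 71,1955.2,0.3218,"Datong Shanxi, China"
Sample 72,1756.4,0.3004,"Datong Shanxi, China"
Sample 73,886.5,0.1938,"Datong Shanxi, China"
Sample 74,1069.2,0.2186,"Datong Shanxi, China"
Sample 75,1522.4,0.2741,"Datong Shanxi, China"
Sample 76,1633.7,0.2868,"Gansu, China"
Sample 77,1563.2,0.2788,"Gansu, China"
Sample 78,1111.5,0.2241,"Gansu, China"
Sample 79,753.2,0.1746,"Gansu, China"
Sample 80,1028.3,0.2132,"Gansu, China"
Sample 81,1556.3,0.2780,"Gansu, China"
Sample 82,1432.5,0.2636,"Gansu, China"
Sample 83,1775.3,0.3025,"Gansu, China"
Sample 84,981.2,0.2069,"Gansu, China"
Sample 85,1092.5,0.2216,"Gansu, China"
Sample 86,1137.6,0.2274,"Gansu, China"
Sample 87,1523.4,0.2742,"Gansu, China"
Sample 88,1966.2,0.3229,"Gansu, China"
Sample 89,1785.2,0.3035,"Gansu, China"
Sample 90,2114.9,0.3384,"Gansu, China"
Sample 91,1137.9,0.2275,"Gansu, China"
Sample 92,1571.1,0.2797,"Gansu, China"
Sample 93,2538.7,0.3804,"Gansu, China"
Sample 94,2323.2,0.3594,"Gansu, China"
Sample 95,2302.5,0.3573,"Gansu, China"
Sample 96,1233.5,0.2395,"Gansu, China"
Sample 97,1556.2,0.2780,"Gansu, China"
Sample 98,19586.3,1.4083,"Gansu, China"
Sample 99,1445.8,0.2652,"Gansu, China"
Sample 100,1863.5,0.3120,"Gansu, China"
Sample 101,1765.3,0.3014,"Gansu, China"
Sample 102,1554.2,0.2778,"Gansu, China"
Sample 103,2635.8,0.3896,"Gansu, China"
Sample 104,2344.1,0.3614,"Yunnan, China"
Sample 105,2357.6,0.3628,"Yunnan, China"
Sample 106,2212.4,0.3483,"Yunnan, China"
Sample 107,1763.2,0.3011,"Yunnan, China"
Sample 108,1723.4,0.2968,"Yunnan, China"
Sample 109,2563.2,0.3827,"Yunnan, China"
Sample 110,2156.3,0.3426,"Yunnan, China"
Sample 111,1239.5,0.2403,"Yunnan, China"
Sample 112,1452.8,0.2660,"Yunnan, China"
Sample 113,1453.2,0.2661,"Yunnan, China"
Sample 114,1569.5,0.2795,"Yunnan, China"
Sample 115,2356.4,0.3626,"Yunnan, China"
Sample 116,1456.7,0.2665,"Yunnan, China"
Sample 117,3566.5,0.4729,"Yunnan, China"
Sample 118,1752.5,0.3000,"Yunnan, China"
Sample 119,1456.2,0.2664,"Yunnan, China"
Sample 120,2681.1,0.3939,"Yunnan, China"
Sample 121,2959.6,0.4196,"Shanxi, China"
Sample 122,3070.9,0.4297,"Shanxi, China"
Sample 123,4137.4,0.5201,"Shanxi, China"
Sample 124,4065.1,0.5143,"Shanxi, China"
Sample 125,3907.1,0.5014,"Shanxi, China"
Sample 126,1032,0.2137,"Shanxi, China"
Sample 127,4034.4,0.5118,"Shanxi, China"
Sample 128,2258.1,0.3529,"Shanxi, China"
Sample 129,1352.7,0.2541,"Shanxi, China"
Sample 130,1978.3,0.3242,"Shanxi, China"
Sample 131,2054.1,0.3321,"Sichuan, China"
Sample 132,1784.2,0.3034,"Sichuan, China"
Sample 133,2689.7,0.3947,"Sichuan, China"
Sample 134,1212.5,0.2369,"Sichuan, China"
Sample 135,1859,0.3115,"Sichuan, China"
Sample 136,1611.3,0.2843,"Sichuan, China"
Sample 137,849.1,0.1886,"Sichuan, China"
Sample 138,2675.1,0.3933,"Sichuan, China"
Sample 139,3460.7,0.4639,"Sichuan, China"
Sample 140,1623,0.2856,"Sichuan, China"
Sample 141,1322.8,0.2505,"Sichuan, China"
Sample 142,1578,0.2805,"Sichuan, China"
Sample 143,1530,0.2750,"Sichuan, China"
Sample 144,670.1,0.1620,"Sichuan, China"
Sample 145,727.7,0.1708,"Sichuan, China"
Sample 146,702,0.1669,"Sichuan, China"
Sample 147,900.9,0.1959,"Sichuan, China"
Sample 148,873.5,0.1920,"Sichuan, China"
Sample 149,1025.6,0.2128,"Sichuan, China"
Sample 150,735.2,0.1719,"Sichuan, China"
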