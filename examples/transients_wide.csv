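time,leaf_a,leaf_b
0.01,500.05,425.042
0.013434,500.09,425.076
0.018047,500.163,425.139
0.024245,500.294,425.25
0.03257,500.53,425.45
0.043755,500.957,425.813
0.05878,501.726,426.467
0.078965,503.113,427.646
0.106082,505.611,429.769
0.14251,510.103,433.588
0.191448,518.16,440.436
0.257191,532.536,452.656
0.345511,557.959,474.265
0.464159,602.216,511.884
0.623551,677.185,575.607
0.837678,798.489,678.716
1.125336,980.93,833.79
1.511775,1227.222,1043.139
2.030918,1515.34,1288.039
2.728333,1800.932,1530.792
3.665241,2041.126,1734.957
4.923883,2216.76,1884.246
6.614741,2332.478,1982.606
8.886238,2403.574,2043.038
11.937766,2445.396,2078.587
16.037187,2469.371,2098.965
21.544347,2482.912,2110.475
28.942661,2490.495,2116.921
38.881552,2494.722,2120.514
52.233451,2497.072,2122.511
70.170383,2498.377,2123.62
94.266846,2499.1,2124.235
126.638017,2499.501,2124.576
170.125428,2499.724,2124.765
228.546386,2499.847,2124.87
307.029063,2499.915,2124.928
412.462638,2499.953,2124.96
554.102033,2499.974,2124.978
744.380301,2499.986,2124.988
1000.0,2499.992,2124.993
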