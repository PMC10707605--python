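n_clusters,xie_beni:128,calinski_harabasz:128,c_index:128,hartigan:128,dunn:128,mclain_rao:128,xie_beni:64,calinski_harabasz:64,c_index:64,hartigan:64,dunn:64,mclain_rao:64
8,210.56600,3417.12372,0.11338,0.46719,0.00697,0.49971,208.66015,1556.83725,0.11185,-0.31895,0.00734,0.52964
9,123.37128,3068.88135,0.11750,0.49330,0.01016,0.49636,94.03908,2684.95843,0.11189,0.35966,0.01075,0.49275
10,269.10936,1854.72219,0.10734,0.10758,0.00727,0.51922,99.14787,2934.73878,0.09697,0.56646,0.00873,0.45613
11,109.27157,3268.10641,0.10647,0.77948,0.00763,0.45388,85.44762,3297.37070,0.08767,0.78839,0.01132,0.44574
12,197.86335,2415.86019,0.11046,0.57270,0.00592,0.47768,108.40803,2784.55430,0.08885,0.71473,0.00957,0.44275
13,83.87588,3405.33049,0.09428,1.00307,0.01360,0.42899,76.72227,2862.23775,0.08772,0.82933,0.01146,0.44423
14,77.13336,3458.73942,0.08816,1.09874,0.01128,0.43028,91.36067,2692.61013,0.08332,0.84834,0.01307,0.43151
15,89.88902,3335.13698,0.09366,1.13652,0.01060,0.42482,164.86141,2097.78152,0.10025,0.67289,0.00670,0.46676
16,88.22176,2616.69806,0.10316,0.96298,0.01104,0.44847,113.37091,2320.94120,0.07896,0.84304,0.01060,0.43344
17,107.32371,2582.27002,0.08943,1.01434,0.00704,0.42538,740.29343,1267.71892,0.07132,0.30289,0.00335,0.45157
18,130.49625,2536.53023,0.09558,1.05716,0.00981,0.42538,182.85043,1317.30883,0.07615,0.40195,0.00674,0.46498
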