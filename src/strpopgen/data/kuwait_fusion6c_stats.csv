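statistic,CSF1PO,D10S1248,D12S391,D13S317,D16S539,D18S51,D19S433,D1S1656,D21S11,D22S1045,D2S1338,D2S441,D3S1358,D5S818,D7S820,D8S1179,FGA,PentaE,PentaD,TH01,TPOX,vWA,SE33
alleles_2n,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800,800
n_variants,8,10,17,8,8,18,15,15,17,10,14,12,8,7,9,11,20,24,16,7,8,8,45
Ho,0.725,0.763,0.87,0.753,0.788,0.86,0.823,0.895,0.853,0.705,0.848,0.72,0.78,0.728,0.775,0.835,0.838,0.9,0.838,0.78,0.653,0.808,0.94
He,0.722,0.768,0.885,0.766,0.789,0.879,0.844,0.875,0.844,0.716,0.883,0.737,0.77,0.758,0.793,0.835,0.864,0.912,0.849,0.791,0.661,0.809,0.949
HWE_p,0.919,0.052,0.599,0.719,0.084,0.108,0.957,0.38,0.478,0.558,0.559,0.578,0.507,0.125,0.136,0.077,0.366,0.359,0.484,0.593,0.339,0.961,0.778
RMP,0.13,0.094,0.026,0.09,0.078,0.029,0.042,0.03,0.046,0.122,0.026,0.109,0.097,0.098,0.076,0.055,0.035,0.016,0.041,0.077,0.161,0.067,0.007
DP,0.87,0.906,0.974,0.91,0.922,0.971,0.958,0.97,0.954,0.878,0.974,0.891,0.903,0.902,0.924,0.945,0.965,0.984,0.959,0.923,0.839,0.933,0.993
PE,0.468,0.531,0.735,0.514,0.576,0.715,0.641,0.785,0.7,0.436,0.69,0.46,0.562,0.472,0.553,0.666,0.67,0.795,0.67,0.562,0.359,0.613,0.878
TPI,1.818,2.105,3.846,2.02,2.353,3.571,2.817,4.762,3.39,1.695,3.279,1.786,2.273,1.835,2.222,3.03,3.077,5,3.077,2.273,1.439,2.597,8.333
PIC,0.67,0.732,0.873,0.731,0.758,0.865,0.825,0.861,0.824,0.675,0.87,0.698,0.731,0.718,0.761,0.813,0.848,0.905,0.83,0.758,0.616,0.78,0.945
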