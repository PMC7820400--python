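allele,CSF1PO,D10S1248,D12S391,D13S317,D16S539,D18S51,D19S433,D1S1656,D21S11,D22S1045,D2S1338,D2S441,D3S1358,D5S818,D7S820,D8S1179,FGA,PentaE,PentaD,TH01,TPOX,vWA,SE33
2.2,,,,,,,,,,,,,,,,,,,0.025,,,,
3.2,,,,,,,,,,,,,,,,,,,0.001,,,,
5,,,,,,,,,,,,,,,,,,0.07,0.001,,,,
6,,,,,,,,,,,,,,,,,,,0.003,0.279,0.003,,
6.3,,,,,,,,,,,,,,,,,,,,,,,0.001
7,0.001,,,,,,,,,,,,,,0.02,,,0.116,0.009,0.224,,,
8,0.003,,,0.119,0.043,,,,,,,0.001,,0.016,0.17,0.009,,0.041,0.023,0.121,0.51,,
9,0.024,0.006,,0.043,0.168,,0.001,0.001,,,,,,0.063,0.093,0.009,,0.014,0.214,0.228,0.149,,
9.1,,,,,,,,,,,,0.001,,,0.001,,,,,,,,
9.3,,,,,,,,,,,,,,,,,,,,0.123,,,
10,0.29,,,0.059,0.088,0.008,0.001,0.006,,0.009,,0.14,,0.103,0.286,0.078,,0.059,0.183,0.025,0.098,,
10.2,,,,,,,,,,,,,,,,,,0.001,,,,,
10.3,,,,,,,,,,,,,,,,,,,,0.001,,,
10.4,,,,,,,,,,,,,,,,,,,0.001,,,,
11,0.264,0.016,,0.31,0.313,0.024,0.008,0.098,,0.159,,0.395,,0.279,0.255,0.085,,0.115,0.19,,0.218,,0.003
11.2,,,,,,,,,,0.001,,,,,,,,,,,,,
11.3,,,,,,,,,,,,0.07,,,,,,,,,,,
12,0.348,0.026,,0.328,0.249,0.115,0.093,0.114,,0.014,,0.055,,0.333,0.151,0.12,,0.164,0.118,,0.021,,0.006
12.2,,,,,,,0.01,,,,,,,,,,,,,,,,0.003
12.3,,,,,,,,,,,,0.003,,,,,,,,,,,
13,0.061,0.21,,0.106,0.12,0.17,0.249,0.094,,0.01,,0.025,0.005,0.2,0.023,0.253,,0.1,0.125,,0.001,0.004,0.023
13.2,,,,,,,0.03,,,,,,,,,,,,,,,,0.001
13.3,,,,,,,,,,,,0.003,,,,,,,,,,,0.001
14,0.01,0.345,,0.035,0.019,0.144,0.235,0.123,,0.076,0.004,0.281,0.061,0.008,0.001,0.189,,0.046,0.069,,0.001,0.083,0.041
14.2,,,,,,,0.049,,,,,,,,,,,,,,,,
14.3,,,,,,,,,,,,,,,,,,,,,,,0.001
14.4,,,,,,,,,,,,,,,,,,0.001,,,,,
15,,0.224,0.018,0.001,0.003,0.148,0.126,0.139,,0.436,0.003,0.021,0.234,,,0.191,,0.071,0.035,,,0.123,0.031
15.1,,,,,,0.001,,,,,,,,,,,,,,,,,
15.2,,,,,,0.001,0.084,,,,,,,,,,,,,,,,0.001
15.3,,,,,,,,0.029,,,,,,,,,,,,,,,
15.4,,,,,,,,,,,,,,,,,,0.003,,,,,
16,,0.134,0.015,,,0.133,0.061,0.226,,0.248,0.041,0.005,0.266,,,0.05,,0.048,0.004,,,0.245,0.06
16.2,,,,,,0.001,0.04,,,,,,,,,,,,,,,,
16.3,,,,,,,,0.043,,,,,,,,,,,,,,,0.001
16.4,,,,,,,,,,,,,,,,,,0.001,,,,,
17,,0.03,0.128,,,0.1,0.01,0.058,,0.043,0.189,,0.286,,,0.015,,0.056,,,,0.249,0.073
17.2,,,,,,0.001,0.004,,,,,,,,,,0.001,,,,,,
17.3,,,0.004,,,,,0.059,,,,,,,,,,,,,,,0.003
17.4,,,,,,,,,,,,,,,,,,0.001,,,,,
18,,0.008,0.194,,,0.085,,0.001,,0.005,0.12,,0.14,,,0.003,0.008,0.033,0.001,,,0.205,0.089
18.3,,,0.019,,,,,0.009,,,,,,,,,,,,,,,
18.4,,,,,,,,,,,,,,,,,,0.001,,,,,
19,,0.001,0.126,,,0.046,,,,,0.119,,0.006,,,,0.06,0.025,,,,0.081,0.088
19.1,,,0.001,,,,,,,,,,,,,,,,,,,,
19.2,,,,,,,,,,,,,,,,,0.003,,,,,,0.001
19.3,,,0.01,,,,,0.003,,,,,,,,,,,,,,,0.001
20,,,0.095,,,0.01,,,,,0.156,,0.001,,,,0.086,0.025,,,,0.011,0.044
20.2,,,,,,,,,,,,,,,,,,,,,,,0.003
21,,,0.103,,,0.008,,,,,0.048,,,,,,0.143,0.005,,,,,0.016
21.2,,,,,,,,,,,,,,,,,0.003,,,,,,0.02
22,,,0.105,,,0.003,,,,,0.05,,,,,,0.171,0.003,,,,,0.008
22.1,,,,,,,,,,,,,,,,,,,,,,,0.004
22.2,,,,,,,,,,,,,,,,,0.003,,,,,,0.014
23,,,0.114,,,0.004,,,,,0.115,,,,,,0.179,0.001,,,,,
23.2,,,,,,,,,,,,,,,,,0.003,,,,,,0.033
24,,,0.039,,,,,,,,0.085,,,,,,0.17,,,,,,0.001
24.2,,,,,,,,,,,,,,,,,0.003,,,,,,0.028
25,,,0.024,,,,,,,,0.054,,,,,,0.118,,,,,,
25.2,,,,,,,,,,,,,,,,,0.001,,,,,,0.026
26,,,0.005,,,,,,,,0.011,,,,,,0.04,,,,,,
26.2,,,,,,,,,,,,,,,,,,,,,,,0.059
27,,,0.003,,,,,,0.02,,0.006,,,,,,0.008,,,,,,
27.2,,,,,,,,,,,,,,,,,,,,,,,0.074
28,,,,,,,,,0.144,,,,,,,,0.001,,,,,,
28.2,,,,,,,,,,,,,,,,,,,,,,,0.058
29,,,,,,,,,0.23,,,,,,,,0.001,,,,,,
29.2,,,,,,,,,0.001,,,,,,,,,,,,,,0.053
30,,,,,,,,,0.224,,,,,,,,0.001,,,,,,
30.2,,,,,,,,,0.019,,,,,,,,,,,,,,0.053
31,,,,,,,,,0.051,,,,,,,,,,,,,,0.001
31.2,,,,,,,,,0.114,,,,,,,,,,,,,,0.036
32,,,,,,,,,0.006,,,,,,,,,,,,,,
32.2,,,,,,,,,0.119,,,,,,,,,,,,,,0.019
33,,,,,,,,,0.003,,,,,,,,,,,,,,0.006
33.2,,,,,,,,,0.054,,,,,,,,,,,,,,0.005
34,,,,,,,,,0.003,,,,,,,,,,,,,,0.006
34.2,,,,,,,,,0.009,,,,,,,,,,,,,,0.001
35,,,,,,,,,0.001,,,,,,,,,,,,,,0.003
35.2,,,,,,,,,0.003,,,,,,,,,,,,,,
36,,,,,,,,,0.001,,,,,,,,,,,,,,0.004
38,,,,,,,,,,,,,,,,,,,,,,,0.001
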