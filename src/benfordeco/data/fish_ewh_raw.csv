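value
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.01
0.10
0.11
0.11
0.11
0.12
0.14
0.14
0.14
0.15
0.16
0.16
0.16
0.17
0.17
0.18
0.19
1.06
1.08
1.10
1.20
1.20
1.52
1.68
1.71
1.98
10.52
11.03
12.00
14.11
14.72
15.80
16.94
18.22
19.50
114.50
0.02
0.02
0.02
0.02
0.02
0.02
0.02
0.02
0.02
0.02
0.20
0.20
0.21
0.29
2.00
2.00
2.07
2.23
2.25
2.41
2.49
2.80
2.80
2.85
21.01
21.30
21.35
0.03
0.03
0.03
0.03
0.03
0.03
0.03
0.32
0.34
3.20
3.20
3.60
3.68
3.70
32.99
33.60
34.30
38.03
0.04
0.04
0.04
0.04
0.04
0.04
0.40
0.46
0.48
4.00
4.01
4.80
44.90
48.17
0.05
0.05
0.05
0.56
0.56
5.10
5.20
5.51
5.67
53.85
0.06
0.06
0.60
0.63
0.64
0.64
0.69
6.30
6.70
62.25
67.50
0.07
0.73
0.76
70.18
0.08
0.08
0.87
80.82
0.09
0.09
0.90
0.99
9.00
9.31
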