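subject,weight_kg,dose_mg_per_kg,time_h,conc_mg_per_L
1,79.6,4.02,0.0,0.74
1,79.6,4.02,0.25,2.84
1,79.6,4.02,0.57,6.57
1,79.6,4.02,1.12,10.5
1,79.6,4.02,2.02,9.66
1,79.6,4.02,3.82,8.58
1,79.6,4.02,5.1,8.36
1,79.6,4.02,7.03,7.47
1,79.6,4.02,9.05,6.89
1,79.6,4.02,12.12,5.94
1,79.6,4.02,24.37,3.28
2,72.4,4.4,0.0,0.0
2,72.4,4.4,0.27,1.72
2,72.4,4.4,0.52,7.91
2,72.4,4.4,1.0,8.31
2,72.4,4.4,1.92,8.33
2,72.4,4.4,3.5,6.85
2,72.4,4.4,5.02,6.08
2,72.4,4.4,7.03,5.4
2,72.4,4.4,9.0,4.55
2,72.4,4.4,12.0,3.01
2,72.4,4.4,24.3,0.9
3,70.5,4.53,0.0,0.0
3,70.5,4.53,0.27,4.4
3,70.5,4.53,0.58,6.9
3,70.5,4.53,1.02,8.2
3,70.5,4.53,2.02,7.8
3,70.5,4.53,3.62,7.5
3,70.5,4.53,5.08,6.2
3,70.5,4.53,7.07,5.3
3,70.5,4.53,9.0,4.9
3,70.5,4.53,12.15,3.7
3,70.5,4.53,24.17,1.05
4,72.7,4.4,0.0,0.0
4,72.7,4.4,0.35,1.89
4,72.7,4.4,0.6,4.6
4,72.7,4.4,1.07,8.6
4,72.7,4.4,2.13,8.38
4,72.7,4.4,3.5,7.54
4,72.7,4.4,5.02,6.88
4,72.7,4.4,7.02,5.78
4,72.7,4.4,9.02,5.33
4,72.7,4.4,11.98,4.19
4,72.7,4.4,24.65,1.15
5,54.6,5.86,0.0,0.0
5,54.6,5.86,0.3,2.02
5,54.6,5.86,0.52,5.63
5,54.6,5.86,1.0,11.4
5,54.6,5.86,2.02,9.33
5,54.6,5.86,3.5,8.74
5,54.6,5.86,5.02,7.56
5,54.6,5.86,7.02,7.09
5,54.6,5.86,9.1,5.9
5,54.6,5.86,12.0,4.37
5,54.6,5.86,24.35,1.57
6,80.0,4.0,0.0,0.0
6,80.0,4.0,0.27,1.29
6,80.0,4.0,0.58,3.08
6,80.0,4.0,1.15,6.44
6,80.0,4.0,2.03,6.32
6,80.0,4.0,3.57,5.53
6,80.0,4.0,5.0,4.94
6,80.0,4.0,7.0,4.02
6,80.0,4.0,9.22,3.46
6,80.0,4.0,12.1,2.78
6,80.0,4.0,23.85,0.92
7,64.6,4.95,0.0,0.15
7,64.6,4.95,0.25,0.85
7,64.6,4.95,0.5,2.35
7,64.6,4.95,1.02,5.02
7,64.6,4.95,2.02,6.58
7,64.6,4.95,3.48,7.09
7,64.6,4.95,5.0,6.66
7,64.6,4.95,6.98,5.25
7,64.6,4.95,9.0,4.39
7,64.6,4.95,12.05,3.53
7,64.6,4.95,24.22,1.15
8,70.5,4.53,0.0,0.0
8,70.5,4.53,0.25,3.05
8,70.5,4.53,0.52,3.05
8,70.5,4.53,0.98,7.31
8,70.5,4.53,2.02,7.56
8,70.5,4.53,3.53,6.59
8,70.5,4.53,5.05,5.88
8,70.5,4.53,7.15,4.73
8,70.5,4.53,9.07,4.57
8,70.5,4.53,12.1,3.0
8,70.5,4.53,24.12,1.25
9,86.4,3.1,0.0,0.0
9,86.4,3.1,0.3,7.37
9,86.4,3.1,0.63,9.03
9,86.4,3.1,1.05,7.14
9,86.4,3.1,2.02,6.33
9,86.4,3.1,3.53,5.66
9,86.4,3.1,5.02,5.67
9,86.4,3.1,7.17,4.24
9,86.4,3.1,8.8,4.11
9,86.4,3.1,11.6,3.16
9,86.4,3.1,24.43,1.12
10,58.2,5.5,0.0,0.24
10,58.2,5.5,0.37,2.89
10,58.2,5.5,0.77,5.22
10,58.2,5.5,1.02,6.41
10,58.2,5.5,2.05,7.83
10,58.2,5.5,3.55,10.21
10,58.2,5.5,5.05,9.18
10,58.2,5.5,7.08,8.02
10,58.2,5.5,9.38,7.14
10,58.2,5.5,12.1,5.68
10,58.2,5.5,23.7,2.42
11,65.0,4.92,0.0,0.0
11,65.0,4.92,0.25,4.86
11,65.0,4.92,0.5,7.24
11,65.0,4.92,0.98,8.0
11,65.0,4.92,1.98,6.81
11,65.0,4.92,3.6,5.87
11,65.0,4.92,5.02,5.22
11,65.0,4.92,7.03,4.45
11,65.0,4.92,9.03,3.62
11,65.0,4.92,12.12,2.69
11,65.0,4.92,24.08,0.86
12,60.5,5.3,0.0,0.0
12,60.5,5.3,0.25,1.25
12,60.5,5.3,0.5,3.96
12,60.5,5.3,1.0,7.82
12,60.5,5.3,2.0,9.72
12,60.5,5.3,3.52,9.75
12,60.5,5.3,5.07,8.57
12,60.5,5.3,7.07,6.59
12,60.5,5.3,9.03,6.11
12,60.5,5.3,12.05,4.57
12,60.5,5.3,24.15,1.17
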