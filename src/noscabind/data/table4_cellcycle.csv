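compound_id,time_h,sub_g1,g0_g1,s,g2_m
Noscapine,0,0.29,58.85,10.24,24.29
Noscapine,24,7.24,19.48,4.19,62.38
Noscapine,72,30.62,19.05,8.53,37.36
5a,0,0.27,63.37,12.93,19.45
5a,24,8.46,13.47,4.08,66.37
5a,72,41.57,10.74,7.08,39.25
6a,0,1.44,67.06,9.53,20.17
6a,24,8.12,16.28,4.94,63.18
6a,72,44.82,9.06,7.39,37.72
6b,0,0.74,55.39,12.17,28.79
6b,24,7.37,19.42,4.16,64.42
6b,72,43.18,11.38,7.53,35.84
6c,0,0.82,60.66,11.49,24.29
6c,24,8.08,20.72,4.85,63.49
6c,72,36.73,15.38,8.27,38.41
6d,0,0.52,56.82,12.28,28.39
6d,24,7.27,22.73,4.62,59.41
6d,72,45.38,8.29,7.83,36.18
6e,0,0.87,62.57,11.93,23.15
6e,24,8.17,12.84,4.57,68.42
6e,72,45.42,7.02,6.83,38.52
6f,0,1.04,64.26,9.51,22.47
6f,24,9.47,11.82,6.29,67.48
6f,72,50.44,6.38,4.72,37.29
6g,0,0.62,63.32,12.92,21.37
6g,24,10.86,20.94,4.08,62.28
6g,72,40.29,12.76,8.07,37.93
6h,0,0.35,61.16,12.29,25.09
6h,24,11.37,12.25,5.92,68.58
6h,72,48.73,7.19,6.28,36.18
6i,0,0.46,57.41,11.08,27.14
6i,24,12.25,19.57,4.62,63.38
6i,72,40.18,14.37,6.43,37.15
6j,0,0.39,59.15,9.47,24.35
6j,24,8.29,25.71,3.09,66.17
6j,72,27.24,22.16,8.63,39.48
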