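time_min,simulated_C,experimental_C,experimental_pm_C,printed_deviation_pct,printed_deviation_consistent
0.0,34.3,34.3,0.4,0.0,True
0.5,38.56,40.0,2.0,-3.73,True
1.0,40.03,41.4,2.4,-3.42,True
1.5,41.29,42.8,2.7,-1.87,False
2.0,42.25,43.0,3.0,3.66,False
2.5,42.66,43.0,2.9,-0.8,True
3.0,43.05,43.0,3.1,0.12,True
3.5,43.3,43.0,3.0,0.7,True
4.0,43.18,44.0,2.3,-1.9,True
4.5,43.06,44.1,2.3,-2.42,True
5.0,43.07,44.6,2.9,-3.55,True
5.5,43.42,44.1,3.0,-1.57,True
6.0,43.77,44.2,2.7,-0.98,True
6.5,43.97,44.2,2.5,-0.52,True
7.0,43.75,44.4,2.2,-1.49,True
7.5,43.54,44.6,2.1,-2.48,False
8.0,43.46,44.5,2.4,-2.39,True
8.5,43.75,44.7,2.6,-2.17,True
9.0,44.05,44.9,2.3,-1.93,True
9.5,44.2,44.7,1.9,-1.13,True
10.0,43.95,44.2,1.5,-0.57,True
10.5,43.7,44.2,2.3,-1.14,True
11.0,43.59,43.9,2.5,-0.71,True
11.5,43.87,44.5,2.2,-1.44,True
12.0,44.14,44.1,1.6,0.01,False
12.5,44.27,44.5,1.7,-0.52,True
13.0,44.02,44.0,1.6,0.0,False
13.5,43.76,43.4,1.7,0.83,True
14.0,43.64,43.1,1.6,1.25,True
14.5,43.91,42.6,1.1,3.08,False
15.0,44.18,43.1,1.8,2.51,False
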