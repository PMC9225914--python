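run,A_max_burning_temperature_C,B_stick_diameter_mm,C_distance_mm,D_ambient_C
1,600,12,25,17
2,600,15,30,25
3,600,18,35,32
4,625,12,30,32
5,625,15,35,17
6,625,18,25,25
7,650,12,35,25
8,650,15,25,32
9,650,18,30,17
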