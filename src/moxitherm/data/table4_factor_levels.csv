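level,A_max_burning_temperature_C,B_stick_diameter_mm,C_distance_mm,D_ambient_C
1,600,12,25,17
2,625,15,30,25
3,650,18,35,32
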