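level,max_burning_temperature_C,stick_diameter_mm,distance_mm,ambient_C
1,600,12,25,17
2,650,15,30,25
3,700,18,35,32
standard,600,18,35,25
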