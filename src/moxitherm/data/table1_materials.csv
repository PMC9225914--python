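tissue,specific_heat_J_per_kgK,density_kg_per_m3,conductivity_W_per_mK
Skin,3391,1109,0.37
Fat,2348,911,0.21
Muscle,3421,1090,0.49
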