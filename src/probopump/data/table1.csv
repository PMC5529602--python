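species,proboscis_length_mm,food_canal_diameter_um,pump_length_um,pump_width_um,pump_height_um,shape
Acherontia atropos,10.1,494.6,2417.6,2030.3,765.9,rect
Danaus plexippus,14.4,35.0,886.2,606.3,145.6,rect
Manduca sexta,50,82.5,1834.5,2272.2,1227.4,rect
Nadata gibosa,3.58,25.4,598.3,362.8,240.4,rect
Symmerista albifrons,0.35,17.3,298.8,358.8,91.0,rect
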