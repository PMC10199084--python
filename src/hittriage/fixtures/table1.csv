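pubchem_id,label,role,binding_energy_kcal_mol
132210508,A1,analog,−9.35
132210370,A2,analog,−8.92
132210409,A3,analog,−8.56
132210478,A4,analog,−8.55
132210549,A5,analog,−8.31
59876521,A6,analog,−8.11
59876529,A7,analog,−8.10
5318517,AGP,parent,−7.95
5090,Rofecoxib,control,−8.17
2244,Aspirin,control,−5.61
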