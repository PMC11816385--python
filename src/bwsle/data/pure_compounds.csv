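# Melting temperature and enthalpy of fusion for the pure compounds
# shipped with bwsle. Units: kelvin and kJ/mol.
name,tm_K,dhm_kJ_per_mol
Menthol,315.7,12.89
Thymol,323.5,19.65
Caprylic acid,289.5,21.38
Capric acid,304.8,27.5
Lauric acid,317.5,37.83
Myristic acid,327.03,41.29
Palmitic acid,336.8,51.02
Stearic acid,343.7,61.36
Trioctylphosphine oxide,325.9,58.02
Camphor,450.4,5.28
Sobrerol,423.9,34.81
Phenol,314.15,11.8635
Malonic acid,407.46,23.1
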