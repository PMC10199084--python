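label,homo_eV,lumo_eV,hlg_eV,epe_compound,epe_adduct,be_adduct
Peptide,−5.68,−1.02,3.33,−62.08,,
Rofecoxib,−5.57,−2.08,3.49,−43.51,−64.51,−41.08
Aspirin,−5.26,−3.01,2.25,−41.70,−69.25,−34.53
AGP,−5.79,−1.34,4.45,−48.97,−60.62,−50.43
A1,−5.85,−1.04,4.81,−45.97,−60.05,−48.00
A2,−5.98,−1.29,4.69,−46.53,−56.24,−52.37
A3,−5.77,−1.18,4.59,−48.31,−56.58,−53.81
A4,−5.84,−0.93,4.90,−46.65,−59.31,−49.42
A5,−5.62,−1.20,4.42,−43.98,−63.88,−42.18
A6,−5.61,−1.46,4.15,−47.84,−59.86,−50.61
A7,−5.59,−1.19,4.40,−48.98,−63.63,−47.43
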