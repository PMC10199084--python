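label,ki_uM,le,lle,le_scale,fq,lelp
A1,0.135,0.389,4.107,0.404,0.963,7.102
A2,0.280,0.388,4.118,0.416,0.933,6.276
A3,0.515,0.357,3.525,0.404,0.884,7.739
A4,0.525,0.372,3.844,0.416,0.894,6.546
A5,0.783,0.308,2.877,0.369,0.835,10.484
A6,1.100,0.300,3.500,0.369,0.813,8.193
A7,1.122,0.312,3.393,0.380,0.821,8.192
AGP,1.440,0.318,4.261,0.392,0.811,4.969
Rofecoxib,0.995,0.371,2.987,0.429,0.865,8.124
Aspirin,75.604,0.432,2.883,0.559,0.773,2.863
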