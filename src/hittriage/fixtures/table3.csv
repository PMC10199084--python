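label,mw,ha,n_hba,n_hbd,tpsa,logp,npscore,lipinski,pfizer,caco2,pgp_inhibitor,hia,f30,ppb,vd,bbb,fu,cyp_inhibitor,cyp_substrate,cl,t_half,herg,h_ht,ames,skin_sens,igc50,lc50
Rofecoxib,314.06,22,4,1,67.51,3.014,−0.256,Accepted,Rejected,−5.598,0.01,0.005,0.003,0.99,0.626,0.037,0.02,0.146,0.358,0.535,0.116,0.087,0.592,0.006,0.048,3.199,4.275
Aspirin,180.04,13,4,1,63.6,1.237,0.122,Accepted,Accepted,−5.062,0,0.007,0.003,0.59,0.234,0.661,0.61,0.016,0.114,2.736,0.91,0.015,0.258,0.013,0.511,2.661,3.748
AGP,350.21,25,5,3,86.99,1.58,3.02,Accepted,Accepted,−4.793,0,0.245,0.036,0.30,0.612,0.955,0.67,0.167,0.219,8.907,0.249,0.003,0.012,0.327,0.026,4.909,6.605
A1,334.21,24,4,2,66.76,2.763,2.793,Accepted,Accepted,−4.604,0,0.028,0.006,0.57,0.811,0.996,0.52,0.407,0.283,14.47,0.119,0.004,0.017,0.266,0.018,4.825,6.114
A2,320.2,23,4,2,66.76,2.435,2.936,Accepted,Accepted,−4.647,0,0.217,0.049,0.52,0.885,0.987,0.54,0.155,0.252,14.712,0.134,0.004,0.017,0.227,0.022,4.967,6.293
A3,334.21,24,4,2,66.76,2.763,2.793,Accepted,Accepted,−4.604,0,0.028,0.006,0.57,0.811,0.996,0.52,0.407,0.283,14.47,0.119,0.004,0.017,0.266,0.018,4.825,6.114
A4,320.2,23,4,2,66.76,2.435,2.936,Accepted,Accepted,−4.647,0,0.217,0.049,0.52,0.885,0.987,0.54,0.155,0.252,14.712,0.134,0.004,0.017,0.227,0.022,4.967,6.293
A5,388.19,27,4,2,66.76,3.229,2.224,Accepted,Rejected,−4.665,0,0.01,0.007,0.73,0.803,0.987,0.31,0.351,0.32,9.945,0.04,0.005,0.029,0.158,0.018,5.002,6.461
A6,376.19,27,6,1,82.06,2.458,2.591,Accepted,Accepted,−4.732,0.001,0.007,0.501,0.43,0.839,0.995,0.63,0.466,0.26,13.704,0.121,0.001,0.012,0.065,0.032,5.28,6.613
A7,362.21,26,5,1,64.99,2.556,2.741,Accepted,Accepted,−4.822,0.002,0.008,0.02,0.47,0.997,0.983,0.55,0.412,0.246,13.431,0.087,0.002,0.015,0.271,0.023,5.257,6.973
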