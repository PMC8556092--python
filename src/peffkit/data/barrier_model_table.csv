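energy_mev_u,field_cm,alpha,cos_phi,term_2cs_15,term_2c2_15,horizontal_shift,term_8c2_15,term_cs_5,vertical_shift,total_shift
120,3,0.84,0.71,0.07,0.07,0.55,0.27,-0.10,0.21,0.76
120,10,0.19,0.88,0.05,0.10,0.40,0.42,-0.08,0.43,0.83
190,3,0.53,0.77,0.07,0.08,0.43,0.32,-0.10,0.28,0.71
190,10,0.12,0.92,0.05,0.11,0.33,0.45,-0.07,0.48,0.81
260,3,0.39,0.81,0.06,0.09,0.37,0.35,-0.10,0.32,0.69
260,10,0.09,0.94,0.04,0.12,0.25,0.47,-0.06,0.52,0.77
330,3,0.31,0.84,0.06,0.09,0.30,0.37,-0.09,0.36,0.66
330,10,0.07,0.95,0.04,0.12,0.20,0.48,-0.06,0.54,0.74
400,3,0.25,0.86,0.06,0.10,0.30,0.39,-0.09,0.34,0.64
400,10,0.06,0.96,0.04,0.12,0.17,0.49,-0.05,0.55,0.72
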