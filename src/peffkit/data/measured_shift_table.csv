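energy_mev_u,field_cm,shift_ratio,uncertainty
120,3,0.782,0.02
190,3,0.715,0.03
260,3,0.678,0.04
330,3,0.677,0.05
400,3,0.649,0.05
120,5,0.795,0.03
190,5,0.746,0.04
260,5,0.699,0.05
330,5,0.694,0.05
400,5,0.660,0.06
120,8,0.811,0.04
190,8,0.783,0.04
260,8,0.725,0.05
330,8,0.716,0.06
400,8,0.695,0.06
120,10,0.843,0.05
190,10,0.825,0.05
260,10,0.773,0.06
330,10,0.744,0.07
400,10,0.723,0.06
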