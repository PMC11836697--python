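level,predictor,trend_slope,effect_slope,level_total
within,sst,0.033,-6.64,-0.79
within,be,0.058,-3.75,
within,ecf,0.049,-4.44,
within,size,0.21,-0.45,
among,sst,0.038,-4.10,-0.24
among,be,-0.021,-6.04,
among,ecf,-0.0098,-5.60,
among,size,-0.27,0.31,
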