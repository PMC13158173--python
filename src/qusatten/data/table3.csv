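organ,n,measured_mean,measured_std,literature_mean,literature_min,literature_max,printed_rel_error,reproducible
kidney,12,0.066,0.007,0.060,0.051,0.064,10,true
liver,12,0.075,0.008,0.068,0.056,0.079,10,true
pancreas,8,0.098,0.016,0.15,0.066,0.232,35,true
breast,3,0.14,0.014,0.13,0.092,0.17,7.7,true
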