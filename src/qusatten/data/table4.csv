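organ,n,measured_mean,measured_iqr,literature_mean,literature_min,literature_max,printed_rel_error,reproducible
kidney,12,3.2,3.1,1.0,0.90,1.1,220,true
liver,12,3.7,3.4,3.2,0,6.4,16,true
pancreas,8,5.7,5.3,3.4,2.0,6.5,67,false
breast,3,57,37,76,58,93,26,false
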