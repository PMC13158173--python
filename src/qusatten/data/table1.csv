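region,measured_mean,measured_std,reference_mean,reference_std,printed_abs_error,printed_rel_error,printed_cohens_d
weak,0.079,0.030,0.081,0.008,0.002,2.5,0.09
strong,0.10,0.030,0.11,0.011,0.01,9.1,0.44
inclusions,0.078,0.020,0.081,0.008,0.003,3.7,0.20
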