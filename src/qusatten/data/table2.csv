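method,mean,std,printed_p,printed_cohens_d,reproducible
pwi,0.079,0.011,,,
sdm,0.082,0.023,,,
sldm,0.081,0.021,,,
pwi_vs_sdm,,,0.913,0.164,false
pwi_vs_sldm,,,0.636,0.127,false
sdm_vs_sldm,,,0.813,0.0363,false
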