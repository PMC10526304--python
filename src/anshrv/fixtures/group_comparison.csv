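feature,normal_median,ad_median,u_value,p_value
sdnn_ms,36.3,10.9,1,<0.001
rmssd_ms,41.4,10.4,0,<0.001
lf_nu,37.32,69.58,14,<0.001
hf_nu,62.12,29.95,14,<0.001
lf_hf,0.601,2.323,14,<0.001
sd1_ms,29.3,7.4,0,<0.001
sd2_ms,37.8,12.3,6,<0.001
sd2_sd1,1.401,1.68,87.5,0.048
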