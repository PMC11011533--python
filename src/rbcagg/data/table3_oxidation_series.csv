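group,AI_L,AI_L_sd,NA_L,NA_L_sd,AI_H,AI_H_sd,NA_H,NA_H_sd,n_samples
untreated,0.086,0.04,131.5,31.4,0.004,0.001,11.3,1.1,3
h2o2_200mM,0.073,0.01,128.0,13.3,0.005,0.001,9.3,2.8,3
h2o2_300mM,0.140,0.03,114.0,23.9,0.003,0.002,8.4,1.3,3
h2o2_400mM,0.173,0.03,84.2,25.3,0.005,0.002,11.3,2.5,3
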