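group,AI_L,AI_L_sd,NA_L,NA_L_sd,AI_H,AI_H_sd,NA_H,NA_H_sd,n_samples
control,0.085,0.01,119.4,38.7,0.005,0.002,14.4,4.1,8
non_severe_pe,0.107,0.01,92.1,16.7,0.006,0.001,18.1,5.5,7
severe_pe,0.149,0.05,127.0,9.1,0.011,0.002,25.7,5.8,6
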