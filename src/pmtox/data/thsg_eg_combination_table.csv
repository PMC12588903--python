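dose_thsg,dose_eg,f_additive,g_additive,y_obs,ci_d1_printed,ci_d2_printed,judgment
30.00,1.25,8.03,9.62,0.00,0.0000,0.0000,antagonistic
120.00,2.50,19.42,64.88,0.00,0.0000,0.0000,antagonistic
180.00,5.00,33.23,83.70,0.00,0.0000,0.0000,antagonistic
250.00,7.50,42.44,89.90,55.73,1.3132,0.6199,additive
300.00,10.00,49.74,91.71,80.48,1.6180,0.8775,additive
350.00,12.50,56.91,92.59,92.13,1.6189,0.9950,additive
400.00,15.00,65.68,93.05,95.87,1.4596,1.0303,synergistic
450.00,17.50,76.13,93.31,97.92,1.2862,1.0494,synergistic
500.00,20.00,85.59,93.46,99.44,1.1618,1.0640,synergistic
550.00,22.50,92.31,93.55,99.40,1.0769,1.0625,synergistic
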