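Vh_mV,F_R,F_FI,F_SI,rate_per_s
-60,0.118,0.342,0.540,0.0096
-80,0.832,0.100,0.069,0.0040
-100,0.985,0,0.015,0.0020
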