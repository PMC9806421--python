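subunit_type,gene,log2_level,fraction_pct
alpha,Scn1a,3.72,3.0
alpha,Scn2a,7.54,42.4
alpha,Scn3a,6.31,18.1
alpha,Scn4a,4.88,6.7
alpha,Scn5a,4.77,6.2
alpha,Scn7a,4.80,6.4
alpha,Scn8a,5.72,12.0
alpha,Scn9a,3.39,2.4
alpha,Scn10a,2.73,1.5
alpha,Scn11a,2.46,1.3
beta,Scn1b,11.34,39.5
beta,Scn2b,6.51,1.4
beta,Scn3b,11.91,58.7
beta,Scn4b,4.70,0.4
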