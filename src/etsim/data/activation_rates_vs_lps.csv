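# Empirical monocyte activation rates estimated from one-phase decay fits
# of two-stimulus tolerization assays, per priming LPS dose.
lps_ng_ml,rate_per_h
5,4.6581
2,4.4318
1,3.7784
0.5,3.7100
0.1,1.5527
0.05,0.1177
0.005,0.0124
0.0005,0.0000
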