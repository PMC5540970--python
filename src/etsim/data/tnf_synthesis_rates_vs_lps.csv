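# Estimated per-cell TNF synthesis rates vs LPS concentration,
# recovered from dose-response time-course optimization.
lps_ng_ml,rate_pg_per_h_per_monocyte
5,0.007043
0.25,0.005270
0.1,0.002359
0.05,0.001136
0.001,0.0000
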