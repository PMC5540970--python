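{
  "max_activation_rate": 4.4990,
  "ac50": 0.1889,
  "hill_n": 1.4825,
  "immunomodulation_rate": 0.1088,
  "lps_removal_rate": 0.0726,
  "max_tnf_synthesis_rate": 0.0071,
  "sc50": 0.0890,
  "hill_m": 1.7670,
  "tnf_delay_td": 1.0,
  "tnf_degradation_rate": 0.1362,
  "ccl2_synth_resting": 0.0001315,
  "ccl2_synth_inflammatory": 0.0001315,
  "ccl2_synth_et": 0.004633,
  "ccl2_degradation_rate": 0.2828
}
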