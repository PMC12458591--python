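{
 "half_life_h": {
  "Y-86": 14.74,
  "Y-90": 64.05
 },
 "mean_beta_energy_mev": {
  "Y-90": 0.9337
 }
}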