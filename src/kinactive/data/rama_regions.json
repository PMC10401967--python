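{
  "phi_split": 0.0,
  "alpha_psi": [-120.0, 50.0],
  "left_psi": [-50.0, 100.0]
}
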