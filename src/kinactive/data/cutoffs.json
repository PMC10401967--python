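{
  "dfg_anchor_cutoff": 11.0,
  "saltbridge_cutoff": 3.6,
  "actloop_nt_cutoff": 3.6,
  "actloop_ct_cutoff_nontyr": 6.0,
  "actloop_ct_cutoff_tyr": 8.0,
  "spine_cutoff": 5.0
}
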