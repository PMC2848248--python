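{
 "synthetic": true,
 "description": "Synthetic mini-profiles standing in for the WWE (PS50918), PARP catalytic core (PS51059) and RST (PF12174) signatures. Consensus strings generated from a fixed RNG; the PARP_core consensus is the loop-invariant beta1..beta3 region of the packaged fold reference (core coordinates 61..140).",
 "match_weight": 0.7,
 "threshold": 0.8,
 "profiles": {
  "WWE": "KEMCCMNKCYRLYGPHADYNEHIQCWSCAF",
  "PARP_core": "TPQDVSYAVFGMCNHCSMVFIKCRMHNEEDNPFEKDTSTFEKLWTGMPYDEWTKHACVYLHASSSEVSEYVLMEYRSMNV",
  "RST": "SEWGHNQYFLTFRKQGYAHYLYAGESPKRMDFSLKNFHQF"
 },
 "parp_core_offset": 60
}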