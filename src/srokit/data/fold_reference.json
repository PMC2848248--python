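{
 "name": "PARP_core_reference",
 "synthetic": true,
 "description": "Synthetic stand-in for the fold-annotated HsPARP1 catalytic core. Sequence generated from a fixed RNG; fold spans, landmark geometry and full-protein coordinate offset mirror the published HsPARP1 annotation (triad H862/Y896/E988, beta4-beta5 loop of 37 residues).",
 "sequence": "SVYWCEKCMVFRVQHSFTEKDLSAYDLLEEHRIMRWRTGMTPDPSHNTGNLYHKQICNKCTPQDVSYAVFGMCNHCSMVFIKCRMHNEEDNPFEKDTSTFEKLWTGMPYDEWTKHACVYLHASSSEVSEYVLMEYRSMNVMSRPQKWELMNNQRWDQQLKAWNELEAPGIILKIQQCWWISLESAQGWNVQPDRVMHGAMECAMPGLTLEKSPFFWCFDGGTDYEIIGRH",
 "offset": 787,
 "spans": {
  "beta1": [
   68,
   75
  ],
  "beta2": [
   105,
   113
  ],
  "alpha2": [
   120,
   134
  ],
  "beta3": [
   140,
   147
  ],
  "beta4": [
   156,
   163
  ],
  "beta5": [
   201,
   208
  ],
  "beta6": [
   215,
   222
  ]
 }
}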