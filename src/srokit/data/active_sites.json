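{
 "description": "Curated reference table of active-site characteristics of A. thaliana PARPs and SROs and human PARP-family proteins: catalytic triad residues with full-protein positions, beta4-beta5 loop length, experimental NAD-binding evidence and the literature activity class.",
 "columns": [
  "name",
  "identifier",
  "wwe",
  "triad",
  "loop_length",
  "nad_binding",
  "activity"
 ],
 "rows": [
  {
   "name": "AtPARP1",
   "identifier": "At4g02390.1",
   "wwe": "No",
   "triad": [
    "H",
    486,
    "Y",
    520,
    "E",
    614
   ],
   "loop_length": 38,
   "nad_binding": "yes",
   "activity": "PARP"
  },
  {
   "name": "AtPARP2",
   "identifier": "At2g31320.1",
   "wwe": "No",
   "triad": [
    "H",
    833,
    "Y",
    867,
    "E",
    960
   ],
   "loop_length": 36,
   "nad_binding": "yes",
   "activity": "PARP"
  },
  {
   "name": "AtPARP3",
   "identifier": "At5g22470.1",
   "wwe": "No",
   "triad": [
    "C",
    653,
    "V",
    687,
    "E",
    782
   ],
   "loop_length": 36,
   "nad_binding": "yes",
   "activity": "PARP"
  },
  {
   "name": "AtRCD1",
   "identifier": "At1g32230.1",
   "wwe": "Yes",
   "triad": [
    "L",
    333,
    "H",
    365,
    "N",
    428
   ],
   "loop_length": 5,
   "nad_binding": "no",
   "activity": "inactive"
  },
  {
   "name": "AtSRO1",
   "identifier": "At2g35510.1",
   "wwe": "Yes",
   "triad": [
    "V",
    329,
    "H",
    361,
    "N",
    422
   ],
   "loop_length": 5,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "AtSRO2",
   "identifier": "At1g23550.1",
   "wwe": "Yes",
   "triad": [
    "Y",
    118,
    "H",
    153,
    "N",
    216
   ],
   "loop_length": 5,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "AtSRO3",
   "identifier": "At1g70440.1",
   "wwe": "Yes",
   "triad": [
    "Y",
    110,
    "H",
    145,
    "K",
    208
   ],
   "loop_length": 5,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "AtSRO4",
   "identifier": "At3g47720.1",
   "wwe": "Yes",
   "triad": [
    "C",
    129,
    "C",
    150,
    "K",
    214
   ],
   "loop_length": 6,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "AtSRO5",
   "identifier": "At5g62520.1",
   "wwe": "Yes",
   "triad": [
    "C",
    113,
    "Y",
    143,
    "K",
    207
   ],
   "loop_length": 5,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "HsPARP1",
   "identifier": "P09874",
   "wwe": "No",
   "triad": [
    "H",
    862,
    "Y",
    896,
    "E",
    988
   ],
   "loop_length": 37,
   "nad_binding": "yes",
   "activity": "PARP"
  },
  {
   "name": "HsPARP7",
   "identifier": "Q7Z3E1",
   "wwe": "Yes",
   "triad": [
    "H",
    532,
    "Y",
    564,
    "I",
    631
   ],
   "loop_length": 6,
   "nad_binding": "ND",
   "activity": "mART"
  },
  {
   "name": "HsPARP10",
   "identifier": "Q53GL7",
   "wwe": "No",
   "triad": [
    "N",
    886,
    "Y",
    919,
    "I",
    987
   ],
   "loop_length": 6,
   "nad_binding": "yes",
   "activity": "mART"
  },
  {
   "name": "HsPARP11",
   "identifier": "Q9NR21",
   "wwe": "Yes",
   "triad": [
    "H",
    197,
    "Y",
    229,
    "I",
    313
   ],
   "loop_length": 6,
   "nad_binding": "ND",
   "activity": "mART"
  },
  {
   "name": "HsPARP12",
   "identifier": "Q9H0J9",
   "wwe": "Yes",
   "triad": [
    "H",
    564,
    "Y",
    596,
    "I",
    660
   ],
   "loop_length": 6,
   "nad_binding": "ND",
   "activity": "mART"
  },
  {
   "name": "HsPARP13",
   "identifier": "Q7Z2W4",
   "wwe": "Yes",
   "triad": [
    "Y",
    787,
    "Y",
    819,
    "V",
    876
   ],
   "loop_length": 6,
   "nad_binding": "ND",
   "activity": "inactive"
  },
  {
   "name": "HsPARP14",
   "identifier": "NP_060024",
   "wwe": "Yes",
   "triad": [
    "H",
    1682,
    "Y",
    1714,
    "L",
    1782
   ],
   "loop_length": 6,
   "nad_binding": "yes",
   "activity": "mART"
  }
 ]
}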