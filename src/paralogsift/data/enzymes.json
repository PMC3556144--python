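{
  "HindIII": {"site": "AAGCTT", "cut_offset": 1},
  "EcoRI": {"site": "GAATTC", "cut_offset": 1},
  "BamHI": {"site": "GGATCC", "cut_offset": 1},
  "PstI": {"site": "CTGCAG", "cut_offset": 5},
  "SmaI": {"site": "CCCGGG", "cut_offset": 3},
  "XhoI": {"site": "CTCGAG", "cut_offset": 1},
  "KpnI": {"site": "GGTACC", "cut_offset": 5}
}
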