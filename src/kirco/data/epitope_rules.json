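{
  "bw4": {
    "window": [77, 83],
    "patterns": ["NLRIALR", "NLRTALR", "DLRTLLR", "DLRIALR", "DLRTALR"],
    "required_position": 83,
    "required_residue": "R"
  },
  "c1": {
    "position": 80,
    "residue": "N",
    "name_exceptions": ["B*46:01", "B*73:01"]
  },
  "a3_11": {
    "names": ["A*03", "A*11"]
  }
}
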