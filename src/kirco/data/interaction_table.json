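{
  "rules": [
    {"receptor": "KIR2DL2", "epitopes": ["C1"], "hla_exceptions": ["C*04:01", "C*02:02", "C*05:01"]},
    {"receptor": "KIR2DL3", "epitopes": ["C1"]},
    {"receptor": "KIR2DS2", "epitopes": []},
    {"receptor": "KIR2DL1", "epitopes": ["C2"]},
    {"receptor": "KIR2DS1", "epitopes": ["C2"]},
    {"receptor": "KIR3DL1", "epitopes": ["Bw4"]},
    {"receptor": "KIR3DS1", "epitopes": []},
    {"receptor": "KIR3DL2", "epitopes": ["A3/11"]},
    {"receptor": "KIR3DL3", "epitopes": []},
    {"receptor": "KIR2DL4", "epitopes": []},
    {"receptor": "KIR2DL5", "epitopes": []},
    {"receptor": "KIR2DS3", "epitopes": []},
    {"receptor": "KIR2DS4", "epitopes": []},
    {"receptor": "KIR2DS5", "epitopes": []}
  ],
  "kir_nulls": ["KIR3DL1*004"],
  "hla_nulls": []
}
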