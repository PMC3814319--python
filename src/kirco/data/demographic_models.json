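{
  "models": [
    {"label": "constant", "epochs": [[0.0, 1.0]], "theta": 5.0},
    {"label": "ancient_expansion", "epochs": [[0.0, 1.0], [0.5, 0.1]], "theta": 5.0},
    {"label": "bottleneck_expansion", "epochs": [[0.0, 1.0], [0.1, 0.02], [0.3, 1.0]], "theta": 5.0},
    {"label": "repeated_bottleneck", "epochs": [[0.0, 1.0], [0.2, 0.05], [0.4, 1.0], [0.6, 0.05], [0.8, 1.0]], "theta": 5.0},
    {"label": "recent_expansion", "epochs": [[0.0, 10.0], [0.05, 1.0]], "theta": 5.0}
  ]
}
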