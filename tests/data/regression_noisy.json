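[
  {
    "analysis": "crowns",
    "arch": "maxillary",
    "mean_mm": 0.004867766317502301,
    "sd_mm": 0.011189806759445309,
    "max_mm": 0.06198900480098945,
    "n_vertices": 6207
  },
  {
    "analysis": "roots",
    "arch": "maxillary",
    "mean_mm": 0.0012277961838336935,
    "sd_mm": 0.03569030740142878,
    "max_mm": 0.1540078506046783,
    "n_vertices": 5269
  }
]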