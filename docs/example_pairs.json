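[
  {
    "comment": "pore gate: Calpha-Calpha across opposing protomers (Ile4937 pair)",
    "a": ["A", 4937, "CA"],
    "b": ["C", 4937, "CA"]
  },
  {
    "comment": "EF-hand to S2S3 contact of the neighboring protomer (Glu4075 - Phe4732)",
    "a": ["A", 4075, "CA"],
    "b": ["B", 4732, "CA"]
  }
]
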