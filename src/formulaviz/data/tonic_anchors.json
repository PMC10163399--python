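[
  {"herb": "Baishao", "element": "wood", "srgb": "#7A9E7E"},
  {"herb": "Danggui", "element": "fire", "srgb": "#C08081"},
  {"herb": "Baizhu", "element": "earth", "srgb": "#C3AE76"},
  {"herb": "Jiegeng", "element": "metal", "srgb": "#C2C2BC"},
  {"herb": "Shudihuang", "element": "water", "srgb": "#6E6E78"}
]
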