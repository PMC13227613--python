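{
  "thigh": {
    "sitting": ["SittingNotInTransport"],
    "sitting-in-transport": ["SittingInTransport"],
    "cycling": ["Cycling"],
    "upright": ["Standing", "LowStepping", "ModerateStepping", "VigorousStepping"],
    "stepping": ["LowStepping", "ModerateStepping", "VigorousStepping"],
    "lying-primary": ["Lying"],
    "lying-secondary": ["Lying"],
    "sedentary": ["SittingNotInTransport", "SittingInTransport"]
  },
  "api": {
    "STILL": ["Lying", "SittingNotInTransport", "Standing"],
    "IN_VEHICLE": ["SittingInTransport"],
    "ON_FOOT": ["LowStepping", "ModerateStepping", "VigorousStepping"],
    "WALKING": ["LowStepping", "ModerateStepping"],
    "RUNNING": ["VigorousStepping"],
    "ON_BICYCLE": ["Cycling"],
    "TILTING": [],
    "UNKNOWN": []
  }
}
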