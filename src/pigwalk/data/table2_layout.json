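{
  "comment": "Published center-to-center Euclidean distances (meters) between the five antenna locations of the reference fattening pen: feeding trough, three nipple drinkers, playing device.",
  "distance_matrix": {
    "trough": {"drinker1": 7.0, "drinker2": 7.5, "drinker3": 7.3, "playing_device": 5.2},
    "drinker1": {"drinker2": 1.6, "drinker3": 2.7, "playing_device": 3.0},
    "drinker2": {"drinker3": 1.3, "playing_device": 2.6},
    "drinker3": {"playing_device": 2.1},
    "playing_device": {}
  }
}
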