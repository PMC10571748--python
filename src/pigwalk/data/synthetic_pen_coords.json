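{
  "comment": "SYNTHETIC planar embedding of the reference pen's published distance matrix, found once by least-squares multidimensional scaling and frozen. Pairwise distances reproduce the published matrix to within 0.013 m. No real antenna coordinates were published; these exist only so the simulator can carry a geometrically consistent pen.",
  "locations": {
    "trough": [0.0, 0.0],
    "drinker1": [6.9969, 0.0],
    "drinker2": [7.3452, 1.5488],
    "drinker3": [6.7763, 2.7039],
    "playing_device": [4.7883, 2.0289]
  }
}
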