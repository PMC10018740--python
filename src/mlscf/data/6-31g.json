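{
  "name": "6-31g",
  "description": "Split-valence 6-31G basis (Pople lineage) for first-row atoms plus hydrogen and helium. Coefficients refer to normalized primitives.",
  "elements": {
    "H": [
      ["s", [18.73113700, 2.82539370, 0.64012170],
            [0.03349460, 0.23472695, 0.81375733]],
      ["s", [0.16127780], [1.0]]
    ],
    "He": [
      ["s", [38.42163400, 5.77803000, 1.24177400],
            [0.02376600, 0.15467900, 0.46963000]],
      ["s", [0.29796400], [1.0]]
    ],
    "C": [
      ["s", [3047.52490000, 457.36951000, 103.94869000, 29.21015500, 9.28666300, 3.16392700],
            [0.00183470, 0.01403730, 0.06884260, 0.23218440, 0.46794130, 0.36231200]],
      ["s", [7.86827240, 1.88128850, 0.54424930],
            [-0.11933240, -0.16085420, 1.14345640]],
      ["p", [7.86827240, 1.88128850, 0.54424930],
            [0.06899910, 0.31642400, 0.74430830]],
      ["s", [0.16871440], [1.0]],
      ["p", [0.16871440], [1.0]]
    ],
    "N": [
      ["s", [4173.51100000, 627.45790000, 142.90210000, 40.23433000, 12.82021000, 4.39043700],
            [0.00183480, 0.01399500, 0.06858700, 0.23224100, 0.46907000, 0.36045500]],
      ["s", [11.62635800, 2.71628000, 0.77221800],
            [-0.11496100, -0.16911800, 1.14585200]],
      ["p", [11.62635800, 2.71628000, 0.77221800],
            [0.06758000, 0.32390700, 0.74089500]],
      ["s", [0.21203130], [1.0]],
      ["p", [0.21203130], [1.0]]
    ],
    "O": [
      ["s", [5484.67170000, 825.23495000, 188.04696000, 52.96450000, 16.89757000, 5.79963530],
            [0.00183110, 0.01395010, 0.06844510, 0.23271430, 0.47019300, 0.35852090]],
      ["s", [15.53961600, 3.59993360, 1.01376180],
            [-0.11077750, -0.14802630, 1.13076700]],
      ["p", [15.53961600, 3.59993360, 1.01376180],
            [0.07087430, 0.33975280, 0.72715860]],
      ["s", [0.27000580], [1.0]],
      ["p", [0.27000580], [1.0]]
    ]
  }
}
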