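{
  "name": "sto-3g",
  "description": "Minimal STO-3G basis (Hehre, Stewart, Pople lineage). Shells are lists of [angmom, exponents, contraction coefficients]; 'sp' shells are split into an s and a p shell sharing exponents. Coefficients refer to normalized primitives.",
  "elements": {
    "H": [
      ["s", [3.42525091, 0.62391373, 0.16885540],
            [0.15432897, 0.53532814, 0.44463454]]
    ],
    "He": [
      ["s", [6.36242139, 1.15892300, 0.31364979],
            [0.15432897, 0.53532814, 0.44463454]]
    ],
    "C": [
      ["s", [71.61683700, 13.04509600, 3.53051220],
            [0.15432897, 0.53532814, 0.44463454]],
      ["s", [2.94124940, 0.68348310, 0.22228990],
            [-0.09996723, 0.39951283, 0.70011547]],
      ["p", [2.94124940, 0.68348310, 0.22228990],
            [0.15591627, 0.60768372, 0.39195739]]
    ],
    "N": [
      ["s", [99.10616900, 18.05231200, 4.88566020],
            [0.15432897, 0.53532814, 0.44463454]],
      ["s", [3.78045590, 0.87849660, 0.28571440],
            [-0.09996723, 0.39951283, 0.70011547]],
      ["p", [3.78045590, 0.87849660, 0.28571440],
            [0.15591627, 0.60768372, 0.39195739]]
    ],
    "O": [
      ["s", [130.70932000, 23.80886100, 6.44360830],
            [0.15432897, 0.53532814, 0.44463454]],
      ["s", [5.03315130, 1.16959610, 0.38038900],
            [-0.09996723, 0.39951283, 0.70011547]],
      ["p", [5.03315130, 1.16959610, 0.38038900],
            [0.15591627, 0.60768372, 0.39195739]]
    ],
    "F": [
      ["s", [166.67913000, 30.36081200, 8.21682070],
            [0.15432897, 0.53532814, 0.44463454]],
      ["s", [6.46480320, 1.50228120, 0.48858850],
            [-0.09996723, 0.39951283, 0.70011547]],
      ["p", [6.46480320, 1.50228120, 0.48858850],
            [0.15591627, 0.60768372, 0.39195739]]
    ]
  }
}
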