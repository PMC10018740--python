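# Classical-embedding parameter sets.
#
# Fluctuating-charge (FQ) sets carry per-element electronegativity chi and
# chemical hardness eta, both in atomic units; fragment total charges default
# to 0 per solvent molecule.  The "fq-water" values are the Rick-lineage
# aqueous parametrization used throughout the QM/FQ literature for water.
#
# Fixed-charge sets carry per-element point charges in e.
fq:
  fq-water:
    chi: {O: 0.189194, H: 0.012767}
    eta: {O: 0.623700, H: 0.637512}
fixed:
  tip3p-charges:
    q: {O: -0.834, H: 0.417}
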