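"""Physical constants and unit conversions.

All electronic-structure internals are in Hartree atomic units; geometry
crosses the Å -> bohr boundary exactly once, in :mod:`mlscf.system`.
"""

# CODATA-2018 Bohr radius in Å; the single Å <-> bohr conversion factor.
BOHR_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_ANGSTROM

# Free-electron g factor as printed in the EPR literature this package targets.
# Kept at this precision deliberately for reproducibility of hyperfine output.
G_E = 2.0022319

# CODATA-2018 values used by the hyperfine unit chain (SI).
MU_B_SI = 9.2740100783e-24     # Bohr magneton, J/T
MU_N_SI = 5.0507837461e-27     # nuclear magneton, J/T
MU0_OVER_4PI = 1.0e-7          # T*m/A
BOHR_METER = 0.529177210903e-10

HARTREE_EV = 27.211386245988

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

Z_FROM_SYMBOL = {s: z for z, s in enumerate(ELEMENTS) if z > 0}
SYMBOL_FROM_Z = {z: s for z, s in enumerate(ELEMENTS) if z > 0}

# Standard atomic weights (u), used only for centers of mass.
ATOMIC_MASS = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180,
}

# Ground-state multiplicities used by the spherically averaged atomic
# calculations behind the SAD guess.
GROUND_STATE_MULTIPLICITY = {
    1: 2, 2: 1, 3: 2, 4: 1, 5: 2, 6: 3, 7: 4, 8: 3, 9: 2, 10: 1,
}
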