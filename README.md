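# mlscf

Unrestricted multilevel Hartree–Fock and DFT (UMLHF / UMLDFT) with classical
embedding layers, for open-shell molecules — nitroxide-type spin probes in
solution in particular — and the hyperfine coupling constants EPR
spectroscopists measure on them.

## The problem and the model

Hyperfine coupling constants (hcc) of solvated radicals are exquisitely
sensitive to the environment, but converging them requires both a quantum
treatment of the probe's surroundings and averaging over many solvation
snapshots — too expensive for full DFT on every frame. `mlscf` attacks this
with a three-layer description:

1. **Active QM region** — the radical (plus optionally its closest waters),
   whose orbitals are variationally optimized.
2. **Inactive QM region** — the rest of the QM solvent, whose α/β density
   blocks are *frozen* after a single polarizing diagonalization and enter
   the active SCF as a fixed effective field (including exact exchange /
   Pauli repulsion against the active block).
3. **Classical layer** — outer solvent as fixed point charges (TIP3P-style)
   or polarizable fluctuating charges (FQ) that re-equilibrate against the
   QM density every SCF cycle.

The density split is exact linear algebra, not an approximation on top of a
model: each idempotent spin density D^σ is decomposed as
D^σ = D_A^σ + D_B^σ by a partial pivoted Cholesky decomposition with pivots
restricted to active-atom AOs. Because pivoted Cholesky of a projector is
Gram–Schmidt on its columns, both blocks are exactly S-idempotent, mutually
orthogonal, and carry integer electron counts. Active virtuals are
projected atomic orbitals (PAOs). The multilevel Fock matrix

    F^σ = h + 2e_A^σ(D_A) + 2e_B^σ + 2e_non-add^σ

freezes the inactive two-electron operator 2e_B^σ = J(D_B) − c_x K(D_B^σ)
once; only the active block iterates. The isotropic hcc of nucleus X is the
Fermi-contact term, proportional to the α−β spin density at the nucleus,

    A_X ∝ (8π/3) g_e μ_B g_X μ_N ρ^{α−β}(R_X) / (2⟨S_z⟩),

reported in Gauss (the hydrogen atom anchors the convention at 507.7 G for
the exact 1s density).

Everything is self-contained scientific Python: McMurchie–Davidson Gaussian
integrals (numba-accelerated), Becke-grid DFT with sympy-derived
exchange-correlation derivatives (SVWN, PBE, PBE0-style hybrid), a full
unrestricted SCF reference path, the multilevel solver, FQ embedding, a
hyperfine module, and a solvation-snapshot pipeline with a synthetic
snapshot generator. See `docs/methods.md` for the model details and the
design choices.

## Worked example

One synthetic solvation snapshot of the smallest aminoxyl radical H₂NO•
surrounded by 12 rigid waters; the 3 closest waters (by center-of-mass
distance) form the QM shell, 1 of them is active alongside the radical, and
the outer 9 form a polarizable FQ layer:

```python
from mlscf.pipeline import (PipelineConfig, generate_synthetic_snapshots,
                            run_snapshot, H2NO_OOP_QUAD)

frames = generate_synthetic_snapshots(seed=11, n_frames=1, n_waters=12,
                                      box_radius=6.0)
cfg = PipelineConfig(functional_name="hf", embedding="fq", n_qm=3,
                     n_active=1, qm_radius=3.5, droplet_radius=100.0,
                     oop_quad=H2NO_OOP_QUAD)
row = run_snapshot(frames[0], cfg)
for k, v in row.items():
    print(f"{k}: {v}")
```

prints

```
scheme: NO
n_active: 1
embedding: fq
hcc_gauss: 5.321057925998357
energy_hartree: -354.0253921322005
n_qm_waters: 3
n_active_waters: 1
n_classical_waters: 9
oop_deg: -0.2735421380254734
```

`hcc_gauss` is the nitrogen Fermi-contact coupling of the converged
UMLHF/FQ spin density (minimal basis; full PBE0 numbers for real nitroxides
are several times larger), `energy_hartree` the total multilevel energy of
the 13-atom QM region in the FQ field, and `oop_deg` the N-pyramidalization
angle of this frame, the geometric coordinate that dominates hcc_N
fluctuations in solution.

The same machinery is scriptable from a shell through the `mlscf` console
command (`scf`, `hcc`, `ensemble`, `synth` subcommands driven by one YAML
config; see `mlscf --help`).

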