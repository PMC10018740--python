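# Methods

`mlscf` implements unrestricted multilevel Hartree–Fock and Kohn–Sham DFT
(UMLHF / UMLDFT): the α and β one-particle density matrices of an open-shell
system are split into an *active* block, which is variationally optimized,
and an *inactive* block, which is frozen after a single polarizing
diagonalization. The QM system may in turn be embedded in a classical layer
of fixed or fluctuating point charges, and the converged total spin density
feeds a Fermi-contact hyperfine module. This note records the model, its
assumptions, the numerical choices, and what the synthetic solvation
fixtures do and do not emulate.

## Electronic-structure model

The unrestricted energy is the standard expression

    E[D^α, D^β] = Tr[D h] + ½ Tr[D J(D)] − (c_x/2) Σ_σ Tr[D^σ K(D^σ)]
                  + ∫ (ε_c + (1 − c_x) ε_x)[ρ^α, ρ^β] + E_nn ,

with c_x the fraction of exact exchange. Available functionals: plain UHF
(c_x = 1), SVWN (Slater exchange + VWN5), PBE, and the PBE0-style hybrid
(c_x = 0.25 with PBE exchange/correlation). Exchange-correlation energy
densities are written symbolically (sympy) and their derivatives with
respect to (ρ_α, ρ_β, σ_αα, σ_αβ, σ_ββ) are exact symbolic derivatives,
lambdified with common-subexpression elimination. The Fock contribution is
therefore the exact derivative of the quadrature energy — the
finite-difference consistency the test suite enforces at 1e−5. Densities
below 1e−12 a.u. are masked; the spin polarization is clamped marginally
inside |ζ| < 1 to keep the PBE spin-scaling factor differentiable at full
polarization.

Integrals are McMurchie–Davidson over contracted cartesian s/p Gaussians
(STO-3G and 6-31G ship as data files; per-atom basis labels support mixed
assignments such as a radical in one basis and waters in another). The
two-electron tensor is stored in core with Schwarz screening, which caps
practical sizes at roughly 100 AOs — ample for droplet-scale fixtures. DFT
quadrature uses atom-centered grids with Becke fuzzy-cell weights
(heteroatom size adjustment included), a mapped Gauss–Chebyshev radial rule
and a Gauss–Legendre × uniform-φ product angular rule; grid levels 1–4 span
(25, 8) to (70, 20) in (n_radial, n_θ) with 2 n_θ² angular points. Level 2
(the default) integrates electron counts to ~1e−6 relative; level 1 is used
for droplet-scale runs.

## The multilevel protocol

1. **SAD guess.** Spherically averaged unrestricted atomic densities,
   cached per (element, basis), assembled block-diagonally. Atomic spin
   densities are rescaled so the total spin excess matches the molecule
   (a closed-shell molecule gets a spin-balanced guess; a free radical atom
   keeps its full polarization).
2. **One purifying diagonalization.** A single Fock build from the SAD
   density and one diagonalization per spin with integer aufbau occupation
   yields S-idempotent densities. This is deliberately *not* a converged
   SCF: the single step captures the bulk of interfragment polarization
   before the density is frozen. If an embedding layer is present its
   operator enters this initial Fock by default (configurable), so the
   environment polarizes the density before partitioning.
3. **Partition.** Each spin density, expressed in the Löwdin-orthogonalized
   basis D′ = S^{1/2} D S^{1/2}, is an orthogonal projector; a partial
   pivoted Cholesky decomposition with pivots restricted to active-atom AOs
   is then Gram–Schmidt on the projector's columns. Every extracted column
   is an S-orthonormal occupied orbital; the residual stays a projector.
   Hence D_A = L Lᵀ and D_B = D − D_A are exactly S-idempotent, mutually
   S-orthogonal, and carry integer electron counts — all re-checked
   numerically on every partition. The decomposition stops when the largest
   remaining active-AO diagonal falls below τ; pivot ties break to the
   lower AO index. **τ defaults to 0.1**: diagonals of occupied-projector
   columns on their own fragment are O(1) while tails of
   neighbor-fragment orbitals are O(10⁻²) at hydrogen-bonding distances, so
   τ must sit between those scales or the decomposition keeps pulling
   inactive-localized orbitals into the active block. The active occupation
   per spin *emerges* from τ; it is not fixed a priori. Virtuals are
   projected atomic orbitals (active-atom AOs with all occupied components
   projected out, Löwdin-orthonormalized, eigenvalue cutoff 1e−8); a
   pivoted-Cholesky factorization of the virtual projector is available
   behind a flag.
4. **Frozen terms.** The inactive Coulomb + scaled-exchange operator
   2e_B^σ = J(D_B) − c_x K(D_B^σ) and the inactive-block energy are
   computed once; a content hash verifies they never change across SCF
   iterations.
5. **Active-space SCF.** Roothaan iterations with DIIS in the S-orthonormal
   active occupied ⊕ virtual basis. The Fock matrix is
   F^σ = h + 2e_A^σ(D_A) + 2e_B^σ + 2e_non-add^σ with the nonadditive
   exchange-correlation pieces E_xc[ρ_A+ρ_B] − E_xc[ρ_A] − E_xc[ρ_B] and
   v_xc[ρ_A+ρ_B] − v_xc[ρ_A] evaluated on one shared grid (a split over
   different grids would break the energy/Fock consistency). Both vanish
   identically for UMLHF. Convergence: max |[F, D]| in the active space
   ≤ 1e−6 and ΔE ≤ 1e−9 Hartree. The inactive block is bitwise untouched.

Energy bookkeeping: the breakdown reports E_A, E_B, E_int and E_non-add.
When atom-level region information is attached, each block owns its
electrons' attraction to its own nuclei and its own nuclear repulsion, and
all cross pieces (including A–B nuclear repulsion) sit in E_int — so E_A of
a well-separated fragment approaches its isolated-fragment energy. The
coupling uses the Tr D_A G(D_B) = Tr D_B G(D_A) symmetry exactly once.
Whatever the split, the total reduces algebraically to the full
unrestricted energy of D_A + D_B, and the full-active limit reproduces an
independent full-SCF energy to 1e−8 Hartree (tested for both HF and the
hybrid functional).

## Classical embedding

Coupling is purely electrostatic: E_int = Σ_i q_i V_i with V_i the full QM
potential (nuclear + electronic, active and inactive alike) at site i; a
strict density-only mode is available. Fixed layers (e.g. the TIP3P charge
set, shipped as a data file) enter the Fock once. Fluctuating charges
minimize χᵀq + ½ qᵀ J q + qᵀ V under exact per-fragment total-charge
constraints (one Lagrange multiplier per solvent molecule, Q = 0 per
water); the saddle-point system is solved directly by symmetric
factorization and the charges are re-equilibrated against the QM density
every SCF cycle, giving mutual polarization. The kernel is Ohno-damped
Coulomb, J_ij = η̄ / sqrt(1 + (η̄ r_ij)²) with η̄ the geometric mean of the
hardnesses and J_ii = η_i; the kernel function is a single replaceable
routine. The shipped aqueous χ/η set gives an isolated FQ water a dipole of
1.88 D (between the gas-phase 1.85 D and the 2.35 D of TIP3P at the same
geometry). The η → ∞ limit with χ_i = −η q_i^fix reproduces a fixed-charge
layer, which the tests verify.

## Hyperfine couplings

The observable is the α−β spin density at the nucleus evaluated from the
*total* (active + inactive) spin density matrix. The unit chain is written
out in `mlscf/hyperfine.py`: the Fermi-contact energy prefactor
(μ0/4π)(8π/3) g_e μ_B g_X μ_N with ρ converted to m⁻³, divided by g_e μ_B
to land in Tesla, times 1e4 for Gauss; ⟨S_z⟩ = (n_α − n_β)/2 of the total
system. The hydrogen atom pins the convention: the exact 1s density 1/π
bohr⁻³ gives 507.7 G, and the UHF/STO-3G value has the closed form
(Σ_k c_k N_k)² from the shipped contraction, which the tests hold to eight
significant figures. g_e is fixed at the EPR-literature value 2.0022319 for
reproducibility; nuclear g-factors (¹H, ²H, ¹³C, ¹⁴N, ¹⁵N, ¹⁷O) ship as a
CSV with their source noted. The dipolar tensor vanishes in isotropic media
and is returned as an explicit zero-trace placeholder. Couplings are
conventionally reported for active atoms; requesting an inactive nucleus
warns and still evaluates.

## Solvation pipeline and synthetic snapshots

Per frame: carve a spherical droplet around the solute center of mass
(solvent molecules kept whole; distance carried by the water oxygen by
convention — "cm" and "closest-atom" variants are configurable), assign an
inner shell to the QM region (by radius, or a fixed count of closest
waters), pick the n closest waters as active under the "NO" scheme
(N–O-bond midpoint) or "CM" scheme (solute center of mass; ties to the
lower atom index), run the multilevel SCF with the remaining waters as a
classical layer, then evaluate hcc and the out-of-plane angle (the signed
angle between the N–O bond and the C–C–N plane, in (−90°, 90°], positive
on the side of the (a−c)×(b−c) normal). Ensemble summaries use the
unbiased sample standard deviation and se = σ/√N_snap (67 % confidence).

The synthetic generator stands in for classical MD sampling. It packs rigid
waters (r_OH = 0.9572 Å, 104.52°) around a rigid radical
(H₂NO• by default — the smallest aminoxyl, with the H–H–N–O improper
playing the role of the ring nitroxides' C–C–N–O angle) by rejection
sampling: uniform oxygen positions in a sphere, water–water O–O ≥ 2.4 Å,
O-to-solute-heavy-atom ≥ 2.7 Å (a hydration-contact distance: close enough
to hydrogen-bond, no steric clash). The solute's out-of-plane angle is
distorted by a zero-mean normal draw of width 8° per frame, emulating the
pyramidalization spread that dominates the hcc distribution in solution.

Water *orientations* are not uniformly random: each water's dipole is
aligned with the local field of the solute's permanent N–O dipole
(modelled as a 3 D point dipole at the N–O midpoint) with a 30° Gaussian
wobble and a uniform spin about the axis — a Langevin-type orientational
response. This is the one place the generator deliberately adds structure
beyond random packing: molecular-dynamics water is orientationally
polarized by a dipolar solute, and that orientational order is precisely
what makes the outer solvent shift the nitrogen hcc systematically. With
fully random orientations (available via ``hbond_wobble_deg=None``) the
solvent's mean field at the radical averages to zero and the layered
description has nothing systematic to describe.

What the fixtures do *not* emulate: hydrogen-bond network topology,
water–water orientational correlation, thermal disorder consistent with a
force field, solute conformational sampling beyond the one out-of-plane
mode, and bulk-density packing. Passing tests therefore demonstrate the
correctness and internal consistency of the multilevel/embedding machinery
and the *direction and rough magnitude* of the layer effects, not
quantitative solvation shifts for real nitroxides.

## Problem sizes and numerical choices

The shipped study conditions for the solvated-radical demonstration are
H₂NO• + 48 waters (8 QM, 40 FQ), PBE0/STO-3G with grid level 1 — 28 QM
atoms, 68 AOs — which one desk-class core handles in about half a minute
per variant. Per-snapshot partition differences of a few tenths of a Gauss
at strongly pyramidalized geometries are expected (the frozen-density
error grows with the out-of-plane angle); the layered comparison is
therefore read as orderings of shifts, not as exact values. Linear
dependencies in the AO basis are removed by canonical orthogonalization at
1e−10; DIIS keeps the last 8 Fock matrices; degenerate Fermi-level
occupations fall back to lowest-index filling with a warning.

## Known limitations

- s/p basis functions only (no d polarization shells), in-core integrals.
- No analytic nuclear gradients; no linear-scaling Fock builds.
- The dipolar hyperfine tensor is a placeholder; no g-tensor or
  spin–orbit corrections.
- The FQ layer carries charge response only (no induced dipoles, no
  geometric reorientation during the SCF).
- Freeze-and-thaw relaxation of the inactive block and energy-based
  localization refinements of the active orbitals are out of scope.
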