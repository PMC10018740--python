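"""Classical embedding: potentials, the FQ solve and Fock coupling.

The generic oracle for the constrained FQ minimization is a null-space
reduction written directly in the test: eliminate the equality constraints
by parametrizing q = q0 + N y and solve the unconstrained normal equations.
"""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlscf.embedding import (
    EmbeddingCoupler,
    EmbeddingError,
    EmbeddingLayer,
    EmbeddingSite,
    embedding_fock,
    embedding_interaction_energy,
    layer_from_system,
    load_parameter_sets,
    ohno_kernel,
    qm_potential_at_sites,
    solve_fq,
)
from mlscf.initial_density import SpinResolvedDensity, purify_guess, sad_guess
from mlscf.scf import SCFEngine, run_scf
from mlscf.system import Atom, AtomicSystem, functional
from tests.conftest import water_atoms


def _fq_layer(positions, chis, etas, fragments, Q=None):
    sites = [
        EmbeddingSite(position=np.asarray(p, float), kind="fq",
                      chi=c, eta=e, fragment=f)
        for p, c, e, f in zip(positions, chis, etas, fragments)
    ]
    layer = EmbeddingLayer(sites=sites)
    layer.fragment_charges = dict(Q or {})
    return layer


def _nullspace_qp_oracle(J, chi, V, fragments, frag_Q):
    """Constrained quadratic minimizer via explicit null-space reduction."""
    frs = sorted(set(fragments))
    n = len(chi)
    C = np.zeros((len(frs), n))
    for j, f in enumerate(fragments):
        C[frs.index(f), j] = 1.0
    b = np.array([frag_Q.get(f, 0.0) for f in frs])
    q0, *_ = np.linalg.lstsq(C, b, rcond=None)
    _, s, vt = np.linalg.svd(C)
    N = vt[len(frs):].T                       # null space of C
    g = chi + V
    y = np.linalg.solve(N.T @ J @ N, -N.T @ (J @ q0 + g))
    return q0 + N @ y


# -- potentials --------------------------------------------------------------

def test_potential_single_nucleus_coulomb_law(h_atom):
    eng = SCFEngine(h_atom, functional("hf"))
    dens = SpinResolvedDensity(
        D_alpha=np.zeros((1, 1)), D_beta=np.zeros((1, 1)), S=eng.S,
        n_alpha=0, n_beta=0,
    )
    from mlscf.constants import BOHR_ANGSTROM

    site = np.array([[0.0, 0.0, BOHR_ANGSTROM]])  # 1 bohr away, in Å
    v = qm_potential_at_sites(dens, h_atom, eng.basis, site)
    assert v[0] == pytest.approx(1.0, abs=1e-12)


def test_potential_neutral_molecule_decays(water):
    eng = SCFEngine(water, functional("hf"))
    res = run_scf(eng)
    dens = SpinResolvedDensity(res.Da, res.Db, eng.S, 5, 5)
    far = np.array([[0.0, 0.0, 1e4 * 0.529177210903]])
    v = qm_potential_at_sites(dens, water, eng.basis, far)
    assert abs(v[0]) <= 1e-7


def test_potential_matches_grid_quadrature(h_atom):
    """H-atom density potential at 5 bohr vs explicit radial quadrature."""
    eng = SCFEngine(h_atom, functional("hf"))
    res = run_scf(eng)
    dens = SpinResolvedDensity(res.Da, res.Db, eng.S, 1, 0)
    from mlscf.constants import BOHR_ANGSTROM
    from mlscf.basis import build_basis

    site_b = 5.0
    v = qm_potential_at_sites(
        dens, h_atom, eng.basis,
        np.array([[0, 0, site_b * BOHR_ANGSTROM]]),
    )
    sh = eng.basis.shells[0]
    nr, nt = 600, 200
    r = np.linspace(1e-6, 25.0, nr)
    ct, wt = np.polynomial.legendre.leggauss(nt)
    rad = np.exp(-np.outer(r ** 2, sh.exps)) @ sh.coefs
    rho = rad ** 2 * float(res.Da[0, 0])
    dist = np.sqrt(r[:, None] ** 2 - 2 * site_b * np.outer(r, ct)
                   + site_b ** 2)
    elec = 2 * np.pi * np.trapezoid((rho[:, None] / dist * (r ** 2)[:, None])
                                    @ wt, r)
    expected = 1.0 / site_b - elec
    assert v[0] == pytest.approx(expected, abs=1e-6)


def test_potential_site_on_nucleus_raises(water):
    eng = SCFEngine(water, functional("hf"))
    dens = SpinResolvedDensity(np.zeros((7, 7)), np.zeros((7, 7)), eng.S,
                               0, 0)
    with pytest.raises(EmbeddingError, match="coincides"):
        qm_potential_at_sites(dens, water, eng.basis,
                              water.coords_angstrom[:1])


# -- FQ solve ----------------------------------------------------------------

def test_fq_single_site_charge_fixed_by_constraint():
    layer = _fq_layer([[0, 0, 0]], [0.3], [0.7], [0], {0: -0.5})
    sol = solve_fq(layer, np.zeros(1))
    assert sol.q[0] == pytest.approx(-0.5, abs=1e-12)


def test_fq_two_identical_sites_zero_external():
    layer = _fq_layer([[0, 0, 0], [3, 0, 0]], [0.2, 0.2], [0.6, 0.6],
                      [0, 0], {0: 0.0})
    sol = solve_fq(layer, np.zeros(2))
    assert np.abs(sol.q).max() <= 1e-12


def test_fq_two_site_hand_solved_closed_form():
    """Two-site single fragment, Q=0, equal eta: eliminating q2 = -q1 from
    the 3x3 KKT system gives q1 = (chi2-chi1)/(2 (eta - J12)) with the
    Ohno coupling J12 written out by hand."""
    import math

    from mlscf.constants import ANGSTROM_TO_BOHR

    eta = 0.8
    chi1, chi2 = 0.1, 0.4
    sep = 4.0
    layer = _fq_layer([[0, 0, 0], [sep, 0, 0]], [chi1, chi2], [eta, eta],
                      [0, 0], {0: 0.0})
    sol = solve_fq(layer, np.zeros(2))
    j12 = eta / math.sqrt(1.0 + (eta * sep * ANGSTROM_TO_BOHR) ** 2)
    q1 = (chi2 - chi1) / (2 * (eta - j12))
    assert sol.q[0] == pytest.approx(q1, abs=1e-12)
    assert sol.q[1] == pytest.approx(-q1, abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_fq_matches_nullspace_qp_oracle(seed):
    """Random 6-site/2-fragment instances vs the generic constrained
    minimizer; per-fragment conservation is exact."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-4, 4, size=(6, 3))
    chi = rng.uniform(0.0, 0.5, size=6)
    eta = rng.uniform(0.3, 1.2, size=6)
    fragments = [0, 0, 0, 1, 1, 1]
    Q = {0: float(rng.uniform(-1, 1)), 1: float(rng.uniform(-1, 1))}
    V = rng.uniform(-0.2, 0.2, size=6)
    layer = _fq_layer(pos, chi, eta, fragments, Q)
    sol = solve_fq(layer, V)
    for f in (0, 1):
        got = sol.q[np.array(fragments) == f].sum()
        assert got == pytest.approx(Q[f], abs=1e-12)
    J = ohno_kernel(layer)
    q_ref = _nullspace_qp_oracle(J, chi, V, fragments, Q)
    assert np.abs(sol.q - q_ref).max() <= 1e-10
    assert sol.stationarity_residual(layer, V) <= 1e-10


def test_fq_no_sites_raises(water):
    layer = EmbeddingLayer(sites=[EmbeddingSite(
        position=np.zeros(3), kind="fixed", q=0.1)])
    with pytest.raises(EmbeddingError, match="no FQ"):
        solve_fq(layer, np.zeros(1))


def test_fq_nonpositive_hardness_rejected():
    with pytest.raises(EmbeddingError, match="hardness"):
        _fq_layer([[0, 0, 0]], [0.1], [0.0], [0])


# -- interaction energy and Fock ---------------------------------------------

def test_interaction_energy_arithmetic():
    assert embedding_interaction_energy(np.zeros(3), np.zeros(3)) == 0.0
    assert embedding_interaction_energy(
        np.array([1.0, -1.0]), np.array([0.5, 0.5])
    ) == pytest.approx(0.0)
    v = np.array([0.3, -0.1])
    q = np.array([0.2, 0.7])
    assert embedding_interaction_energy(v, -q) == pytest.approx(
        -embedding_interaction_energy(v, q)
    )
    with pytest.raises(ValueError):
        embedding_interaction_energy(np.zeros(2), np.zeros(3))


def test_embedding_fock_trace_identity(water):
    """Tr[(Da+Db) F_emb] equals the electronic part of sum V_i q_i."""
    eng = SCFEngine(water, functional("hf"))
    res = run_scf(eng)
    dens = SpinResolvedDensity(res.Da, res.Db, eng.S, 5, 5)
    solvent = AtomicSystem(
        atoms=water_atoms(oz=3.0), mol_id=np.zeros(3, int),
    )
    layer = layer_from_system(solvent, kind="fixed")
    q = layer.fixed_charges
    F = embedding_fock(layer, q, eng.basis)
    from mlscf.embedding import electronic_potential_at_sites

    v_el = electronic_potential_at_sites(dens, eng.basis,
                                         layer.positions_angstrom)
    lhs = float(np.einsum("mn,mn->", dens.D_total, F))
    assert lhs == pytest.approx(float(v_el @ q), abs=1e-10)
    # zero charges -> zero operator; spin-independent by construction
    assert np.abs(embedding_fock(layer, np.zeros(3), eng.basis)).max() == 0.0


def test_infinite_hardness_fq_reproduces_fixed_charges(water):
    """chi_i = -eta q_i^fix with huge equal eta pins the FQ charges to the
    fixed set; interaction energies agree to 1e-6."""
    eng = SCFEngine(water, functional("hf"))
    res = run_scf(eng)
    dens = SpinResolvedDensity(res.Da, res.Db, eng.S, 5, 5)
    solvent = AtomicSystem(atoms=water_atoms(oz=3.0),
                           mol_id=np.zeros(3, int))
    fixed = layer_from_system(solvent, kind="fixed")     # TIP3P charges
    q_fix = fixed.fixed_charges
    eta = 1e8
    layer = _fq_layer(solvent.coords_angstrom, -eta * q_fix,
                      [eta] * 3, [0, 0, 0], {0: 0.0})
    V = qm_potential_at_sites(dens, water, eng.basis,
                              layer.positions_angstrom)
    sol = solve_fq(layer, V)
    assert np.abs(sol.q - q_fix).max() <= 1e-6
    e_fq = embedding_interaction_energy(V, sol.q)
    e_fix = embedding_interaction_energy(V, q_fix)
    assert e_fq == pytest.approx(e_fix, abs=1e-6)


def test_fq_selfconsistency_at_convergence(water_cation):
    """Re-solving the FQ layer with the converged density moves no charge
    by more than 1e-8 e."""
    eng = SCFEngine(water_cation, functional("hf"))
    solvent = AtomicSystem(atoms=water_atoms(oz=3.2),
                           mol_id=np.zeros(3, int))
    layer = layer_from_system(solvent, kind="fq")
    coupler = EmbeddingCoupler(eng, layer)
    pur = purify_guess(water_cation, sad_guess(water_cation, eng),
                       engine=eng, fock_hook=coupler.hook)
    res = run_scf(eng, D0=(pur.D_alpha, pur.D_beta),
                  fock_hook=coupler.hook)
    q_conv = coupler.last_solution.q
    V = coupler.potentials(res.Da + res.Db)
    sol = solve_fq(layer, V)
    assert np.abs(sol.q - q_conv).max() <= 1e-8


def test_parameter_sets_load():
    params = load_parameter_sets()
    assert params["fixed"]["tip3p-charges"]["q"]["O"] == pytest.approx(
        -0.834
    )
    assert set(params["fq"]["fq-water"]["chi"]) == {"O", "H"}
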