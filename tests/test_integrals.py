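"""Integral engine checks against independent closed forms and invariances.

The s-type oracles below are written directly from the textbook
Gaussian-product formulas (independent of the package's McMurchie-Davidson
recursions); p-function correctness is pinned by rotational invariance of
full matrices and by the quadrature cross-check of the potential integrals.
"""
import math

import numpy as np
import pytest
from scipy.special import erf

from mlscf import integrals as ints
from mlscf.basis import build_basis
from mlscf.constants import BOHR_ANGSTROM
from mlscf.system import Atom, AtomicSystem


# -- independent s-type formulas (Boys F0 via erf) ---------------------------

def _f0(t):
    if t < 1e-12:
        return 1.0 - t / 3.0
    return 0.5 * math.sqrt(math.pi / t) * erf(math.sqrt(t))


def s_overlap(a, b, RA, RB):
    p = a + b
    ab2 = np.dot(RA - RB, RA - RB)
    return (math.pi / p) ** 1.5 * math.exp(-a * b / p * ab2)


def s_kinetic(a, b, RA, RB):
    p = a + b
    mu = a * b / p
    ab2 = np.dot(RA - RB, RA - RB)
    return mu * (3.0 - 2.0 * mu * ab2) * s_overlap(a, b, RA, RB)


def s_nuclear(a, b, RA, RB, RC):
    p = a + b
    P = (a * RA + b * RB) / p
    ab2 = np.dot(RA - RB, RA - RB)
    pc2 = np.dot(P - RC, P - RC)
    return (
        -2.0 * math.pi / p * math.exp(-a * b / p * ab2) * _f0(p * pc2)
    )


def s_eri(a, b, c, d, RA, RB, RC, RD):
    p, q = a + b, c + d
    P = (a * RA + b * RB) / p
    Q = (c * RC + d * RD) / q
    alpha = p * q / (p + q)
    k = math.exp(-a * b / p * np.dot(RA - RB, RA - RB))
    k *= math.exp(-c * d / q * np.dot(RC - RD, RC - RD))
    return (
        2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
        * k * _f0(alpha * np.dot(P - Q, P - Q))
    )


def _contract(basis, f, *shell_ids):
    shells = [basis.shells[i] for i in shell_ids]
    total = 0.0
    idx = [range(len(s.exps)) for s in shells]
    import itertools

    for combo in itertools.product(*idx):
        coef = 1.0
        args = []
        for s, k in zip(shells, combo):
            coef *= s.coefs[k]
            args.append(s.exps[k])
        total += coef * f(*args, *[s.center for s in shells])
    return total


@pytest.fixture(scope="module")
def h2():
    r = 1.4 * BOHR_ANGSTROM
    return build_basis(AtomicSystem(
        atoms=[Atom("H", 1, (0, 0, 0)), Atom("H", 1, (0, 0, r))]
    ))


def test_s_type_one_electron_against_closed_forms(h2):
    S, T = ints.overlap_kinetic(h2)
    assert S[0, 0] == pytest.approx(1.0, abs=1e-10)
    assert S[0, 1] == pytest.approx(_contract(h2, s_overlap, 0, 1), abs=1e-12)
    assert T[0, 1] == pytest.approx(_contract(h2, s_kinetic, 0, 1), abs=1e-12)
    sys2 = AtomicSystem(
        atoms=[Atom("H", 1, (0, 0, 0)),
               Atom("H", 1, (0, 0, 1.4 * BOHR_ANGSTROM))]
    )
    V = ints.nuclear_attraction(h2, sys2.coords_bohr, sys2.charges)
    ref = sum(
        _contract(h2, lambda a, b, RA, RB, RC=RC: s_nuclear(a, b, RA, RB, RC),
                  0, 1)
        for RC in sys2.coords_bohr
    )
    assert V[0, 1] == pytest.approx(ref, abs=1e-12)


def test_s_type_eri_against_closed_form(h2):
    eri = ints.eri_tensor(h2)
    ref = _contract(h2, s_eri, 0, 0, 0, 1)
    assert eri[0, 0, 0, 1] == pytest.approx(ref, abs=1e-12)
    ref2 = _contract(h2, s_eri, 0, 1, 0, 1)
    assert eri[0, 1, 0, 1] == pytest.approx(ref2, abs=1e-12)


def test_eri_eightfold_symmetry(h2):
    eri = ints.eri_tensor(h2)
    n = h2.nao
    rng = np.random.default_rng(0)
    for _ in range(20):
        m, nu, l, s = rng.integers(0, n, 4)
        v = eri[m, nu, l, s]
        for perm in ((nu, m, l, s), (m, nu, s, l), (l, s, m, nu),
                     (s, l, nu, m)):
            assert eri[perm] == pytest.approx(v, abs=1e-14)


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def test_rotation_invariance_with_p_functions():
    """Total HF energy of water is invariant under rigid rotation — a strong
    end-to-end check of every p-shell integral class."""
    from mlscf.scf import SCFEngine, run_scf
    from mlscf.system import functional
    from tests.conftest import water_atoms

    base = AtomicSystem(atoms=water_atoms())
    R = _rotation([1.0, 2.0, 0.5], 0.7)
    rotated = AtomicSystem(atoms=[
        Atom(a.symbol, a.Z, tuple(R @ np.array(a.position)))
        for a in base.atoms
    ])
    e1 = run_scf(SCFEngine(base, functional("hf"))).energy
    e2 = run_scf(SCFEngine(rotated, functional("hf"))).energy
    assert e2 == pytest.approx(e1, abs=1e-10)


def test_point_charge_integrals_match_quadrature(h_atom):
    """<mu|1/|r-C||nu> for H at a 5-bohr site vs dense radial quadrature."""
    basis = build_basis(h_atom)
    site = np.array([[0.0, 0.0, 5.0]])
    v = ints.point_charge_integrals(basis, site)[0, 0, 0]
    # radial quadrature of chi(r)^2/|r - C| on a fine spherical grid
    nr, nt = 400, 120
    r = np.linspace(1e-6, 30.0, nr)
    ct, wt = np.polynomial.legendre.leggauss(nt)
    sh = basis.shells[0]
    rad = np.exp(-np.outer(r ** 2, sh.exps)) @ sh.coefs
    dist = np.sqrt(r[:, None] ** 2 - 2 * 5.0 * np.outer(r, ct) + 25.0)
    integrand = (rad ** 2)[:, None] / dist * (r ** 2)[:, None]
    val = 2 * math.pi * np.trapezoid(integrand @ wt, r)
    assert v == pytest.approx(val, abs=1e-6)


def test_ao_index_map_covers_all_aos():
    atoms = [Atom("O", 8, (0, 0, 0)), Atom("H", 1, (1, 0, 0)),
             Atom("N", 7, (0, 3, 0))]
    basis = build_basis(AtomicSystem(atoms=atoms, multiplicity=1))
    covered = []
    for lo, hi in basis.atom_ao_ranges:
        covered.extend(range(lo, hi))
    assert covered == list(range(basis.nao))
    assert basis.nao == 5 + 1 + 5


def test_ao_gradients_match_finite_differences(water):
    basis = build_basis(water)
    pts = np.array([[0.3, -0.2, 0.5], [1.1, 0.7, -0.4]])
    ao = ints.ao_values(basis, pts, deriv=1)
    h = 1e-6
    for ax in range(3):
        shift = np.zeros(3)
        shift[ax] = h
        fd = (
            ints.ao_values(basis, pts + shift)
            - ints.ao_values(basis, pts - shift)
        ) / (2 * h)
        assert np.abs(ao[ax + 1] - fd).max() < 1e-7
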