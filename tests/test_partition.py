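"""Partial pivoted Cholesky partitioning and PAO virtual spaces.

The independent oracle for the restricted pivoted Cholesky is a plain
dense Gram-Schmidt-style factorization written out in the test itself.
"""
import numpy as np
import pytest

from mlscf.basis import build_basis
from mlscf.constants import BOHR_ANGSTROM
from mlscf.initial_density import purify_guess, sad_guess
from mlscf.partition import (
    ActiveOrbitalSpace,
    PartitionedDensity,
    pao_virtuals,
    partial_cholesky_occupied,
    partition_densities,
)
from mlscf.scf import SCFEngine, run_scf
from mlscf.system import Atom, AtomicSystem, define_partition, functional


def test_cholesky_trivial_projector():
    """D = diag(1, 0) in an orthonormal basis, pivot on AO 0."""
    D = np.diag([1.0, 0.0])
    S = np.eye(2)
    L = partial_cholesky_occupied(D, S, [0], tau=1e-6)
    assert L.shape == (2, 1)
    assert np.abs(L - np.array([[1.0], [0.0]])).max() < 1e-12


def test_cholesky_zero_density_gives_zero_columns():
    L = partial_cholesky_occupied(np.zeros((3, 3)), np.eye(3), [0, 1],
                                  tau=1e-6)
    assert L.shape == (3, 0)


def test_cholesky_full_active_recovers_density(purified_dimer):
    D = purified_dimer.D_alpha
    S = purified_dimer.S
    L = partial_cholesky_occupied(D, S, range(D.shape[0]), tau=1e-10)
    assert np.abs(L @ L.T - D).max() <= 1e-8


def test_cholesky_rejects_bad_inputs(purified_dimer):
    D, S = purified_dimer.D_alpha, purified_dimer.S
    with pytest.raises(ValueError, match="tau"):
        partial_cholesky_occupied(D, S, [0], tau=0.0)
    with pytest.raises(ValueError, match="idempotent"):
        partial_cholesky_occupied(D * 0.5, S, [0], tau=1e-6)


def test_cholesky_h2_single_pivot_matches_dense_oracle():
    """H2 sigma_g density, pivot restricted to atom 1's AO: compare with an
    independently coded pivoted rank-1 extraction in the Löwdin basis."""
    r = 1.4 * BOHR_ANGSTROM
    sys_ = AtomicSystem(atoms=[Atom("H", 1, (0, 0, 0)),
                               Atom("H", 1, (0, 0, r))])
    eng = SCFEngine(sys_, functional("hf"))
    res = run_scf(eng)
    D, S = res.Da, eng.S
    L = partial_cholesky_occupied(D, S, [0], tau=1e-6)
    assert L.shape[1] == 1
    # oracle: explicit rank-1 pivoted step on D' = S^1/2 D S^1/2 at pivot 0
    w, V = np.linalg.eigh(S)
    Shalf = (V * np.sqrt(w)) @ V.T
    Sinvh = (V / np.sqrt(w)) @ V.T
    Dp = Shalf @ D @ Shalf
    col = Dp[:, 0] / np.sqrt(Dp[0, 0])
    L_ref = Sinvh @ col[:, None]
    assert np.abs(L @ L.T - L_ref @ L_ref.T).max() < 1e-10


def test_cholesky_is_bitwise_deterministic(purified_dimer):
    D, S = purified_dimer.D_alpha, purified_dimer.S
    L1 = partial_cholesky_occupied(D, S, range(7), tau=0.01)
    L2 = partial_cholesky_occupied(D, S, range(7), tau=0.01)
    assert np.array_equal(L1, L2)


# -- PAOs -------------------------------------------------------------------

def test_pao_no_occupied_gives_lowdin_set(water):
    basis = build_basis(water)
    S, _ = SCFEngine(water, functional("hf")).S, None
    C = pao_virtuals(S, np.zeros((basis.nao, 0)), range(basis.nao))
    assert C.shape[1] == basis.nao
    assert np.abs(C.T @ S @ C - np.eye(basis.nao)).max() < 1e-10


def test_pao_error_when_occupied_spans_space():
    S = np.eye(3)
    C_occ, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))
    with pytest.raises(ValueError, match="virtual"):
        pao_virtuals(S, C_occ, [0, 1, 2])


def test_pao_columns_orthogonal_to_all_occupied(water):
    eng = SCFEngine(water, functional("hf"))
    res = run_scf(eng)
    # all 5 occupied orbitals, active AOs on one H
    C_occ = res.Ca[:, :5]
    basis = eng.basis
    act = basis.aos_on_atoms([1])
    C_virt = pao_virtuals(eng.S, C_occ, act)
    assert np.abs(C_occ.T @ eng.S @ C_virt).max() <= 1e-10
    assert np.abs(
        C_virt.T @ eng.S @ C_virt - np.eye(C_virt.shape[1])
    ).max() <= 1e-10


# -- full partitioning ------------------------------------------------------

def test_partition_all_active_empties_inactive(purified_dimer,
                                               hf_engine_dimer, water_dimer):
    part = define_partition(water_dimer, range(6))
    pd, space = partition_densities(purified_dimer, part,
                                    hf_engine_dimer.basis)
    assert np.abs(pd.D_B_alpha).max() < 1e-10
    assert space.n_occ == (10, 10)


def test_partition_closed_shell_spin_symmetric(purified_dimer,
                                               hf_engine_dimer, water_dimer):
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    assert np.abs(pd.D_A_alpha - pd.D_A_beta).max() < 1e-10
    pd.validate(purified_dimer)


def test_partition_invariants_on_dimer_cation(purified_dimer_cation,
                                              hf_engine_dimer_cation,
                                              water_dimer_cation):
    """All partition invariants hold on the open-shell dimer cation, with
    integer spin traces per block."""
    for active in ([0, 1, 2], [3, 4, 5]):
        part = define_partition(water_dimer_cation, active)
        pd, _ = partition_densities(
            purified_dimer_cation, part, hf_engine_dimer_cation.basis
        )
        pd.validate(purified_dimer_cation)
        for t in pd.traces().values():
            assert t == pytest.approx(round(t), abs=1e-8)


def test_unpaired_electron_localizes_on_active_radical():
    """OH radical + distant water, active = radical: the active block
    carries exactly the unpaired electron."""
    from mlscf.initial_density import purify_guess, sad_guess
    from tests.conftest import water_atoms

    atoms = [Atom("O", 8, (0, 0, 0)), Atom("H", 1, (0.97, 0, 0))]
    atoms += water_atoms(oz=3.2)
    sys_ = AtomicSystem(atoms=atoms, multiplicity=2)
    eng = SCFEngine(sys_, functional("hf"))
    pur = purify_guess(sys_, sad_guess(sys_, eng), engine=eng)
    part = define_partition(sys_, [0, 1])
    pd, _ = partition_densities(pur, part, eng.basis)
    pd.validate(pur)
    tr = pd.traces()
    assert tr["A_alpha"] - tr["A_beta"] == pytest.approx(1.0, abs=1e-8)


def test_repartition_reproduces_active_block(purified_dimer,
                                             hf_engine_dimer, water_dimer):
    part = define_partition(water_dimer, [0, 1, 2])
    pd1, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    pd2, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    assert np.array_equal(pd1.D_A_alpha, pd2.D_A_alpha)


def test_cholesky_virtual_alternative(purified_dimer, hf_engine_dimer,
                                      water_dimer):
    part = define_partition(water_dimer, [0, 1, 2])
    pd, space = partition_densities(
        purified_dimer, part, hf_engine_dimer.basis,
        virtual_method="cholesky",
    )
    S = hf_engine_dimer.S
    for spin in ("alpha", "beta"):
        C_occ, C_virt = space.spin(spin)
        if C_virt.shape[1]:
            assert np.abs(
                C_virt.T @ S @ C_virt - np.eye(C_virt.shape[1])
            ).max() < 1e-8
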