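"""Multilevel Fock/energy assembly and the active-space SCF.

Oracles: the package's own *standard full* unrestricted SCF path (an
independent solver), full-Fock differences for the frozen terms, and
numerical finite-difference gradients of the multilevel energy.
"""
import numpy as np
import pytest

from mlscf.initial_density import purify_guess, sad_guess
from mlscf.multilevel import (
    build_ml_fock,
    frozen_inactive_terms,
    ml_energy,
    run_uml_scf,
)
from mlscf.partition import PartitionedDensity, partition_densities
from mlscf.scf import SCFEngine, run_scf
from mlscf.system import Atom, AtomicSystem, define_partition, functional


def _prep(system, engine, active):
    pur = purify_guess(system, sad_guess(system, engine), engine=engine)
    part = define_partition(system, active)
    pd, space = partition_densities(pur, part, engine.basis)
    return pur, pd, space


# -- frozen inactive terms ---------------------------------------------------

def test_frozen_terms_zero_inactive(purified_dimer, hf_engine_dimer,
                                    water_dimer):
    part = define_partition(water_dimer, range(6))
    pd, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    fr = frozen_inactive_terms(hf_engine_dimer, pd)
    assert np.abs(fr.twoe_B_alpha).max() < 1e-10
    assert fr.E_B_const == pytest.approx(hf_engine_dimer.E_nn, abs=1e-10)


def test_frozen_terms_match_full_fock_difference(purified_dimer,
                                                 hf_engine_dimer,
                                                 water_dimer):
    """UMLHF: 2e_B^s = two-electron part of F_full(D) - F_full(D_A)."""
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    fr = frozen_inactive_terms(eng, pd)
    Fa_full, _, _ = eng.fock(
        pd.D_A_alpha + pd.D_B_alpha, pd.D_A_beta + pd.D_B_beta
    )
    Fa_act, _, _ = eng.fock(pd.D_A_alpha, pd.D_A_beta)
    assert np.abs((Fa_full - Fa_act) - fr.twoe_B_alpha).max() < 1e-10


def test_frozen_terms_recompute_bitwise_identical(purified_dimer,
                                                  hf_engine_dimer,
                                                  water_dimer):
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    f1 = frozen_inactive_terms(hf_engine_dimer, pd)
    f2 = frozen_inactive_terms(hf_engine_dimer, pd)
    assert f1.content_hash == f2.content_hash
    assert np.array_equal(f1.twoe_B_alpha, f2.twoe_B_alpha)


# -- ML Fock -----------------------------------------------------------------

def test_ml_fock_reduces_to_uhf_fock_when_b_empty(purified_dimer,
                                                  hf_engine_dimer,
                                                  water_dimer):
    eng = hf_engine_dimer
    part = define_partition(water_dimer, range(6))
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    fr = frozen_inactive_terms(eng, pd)
    ml = build_ml_fock(eng, pd.D_A_alpha, pd.D_A_beta, fr)
    Fa_ref, Fb_ref, _ = eng.fock(pd.D_A_alpha, pd.D_A_beta)
    assert np.abs(ml.F_alpha - Fa_ref).max() <= 1e-10
    assert np.abs(ml.F_beta - Fb_ref).max() <= 1e-10


def test_ml_fock_swaps_with_spin_for_symmetric_system(purified_dimer,
                                                      hf_engine_dimer,
                                                      water_dimer):
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    fr = frozen_inactive_terms(eng, pd)
    ml = build_ml_fock(eng, pd.D_A_alpha, pd.D_A_beta, fr)
    ml_sw = build_ml_fock(eng, pd.D_A_beta, pd.D_A_alpha, fr)
    assert np.abs(ml.F_alpha - ml_sw.F_beta).max() < 1e-12


@pytest.mark.parametrize("func", ["hf", "pbe0"])
def test_fock_is_derivative_of_energy(ten_ao_radical, func):
    """Finite-difference gradient of the multilevel energy matches the Fock
    matrix elements (diagonal and symmetric off-diagonal perturbations)."""
    spec = functional(func, grid_level=2)
    eng = SCFEngine(ten_ao_radical, spec)
    assert eng.nao == 10
    pur, pd, space = _prep(ten_ao_radical, eng, [0, 1, 2])
    fr = frozen_inactive_terms(eng, pd)
    ml = build_ml_fock(eng, pd.D_A_alpha, pd.D_A_beta, fr)

    def energy_of(DAa):
        part = PartitionedDensity(
            D_A_alpha=DAa, D_A_beta=pd.D_A_beta,
            D_B_alpha=pd.D_B_alpha, D_B_beta=pd.D_B_beta, S=eng.S,
        )
        return ml_energy(eng, part, fr)["total"]

    delta = 1e-6
    for (m, n) in [(0, 0), (1, 4), (2, 7)]:
        P = np.zeros((10, 10))
        P[m, n] = delta
        P[n, m] = delta
        fd = (energy_of(pd.D_A_alpha + P) - energy_of(pd.D_A_alpha - P)) / (
            2 * delta
        )
        expected = ml.F_alpha[m, n] + ml.F_alpha[n, m] if m != n else \
            ml.F_alpha[m, m]
        assert fd == pytest.approx(expected, abs=1e-5)


# -- ML energy ---------------------------------------------------------------

def test_ml_energy_reduces_to_full_expression(purified_dimer,
                                              hf_engine_dimer, water_dimer):
    eng = hf_engine_dimer
    part = define_partition(water_dimer, range(6))
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    bd = ml_energy(eng, pd)
    ref = eng.energy(purified_dimer.D_alpha, purified_dimer.D_beta)
    assert bd["total"] == pytest.approx(ref, abs=1e-10)


def test_nonadditive_term_vanishes_for_umlhf(purified_dimer,
                                             hf_engine_dimer, water_dimer):
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, hf_engine_dimer.basis)
    bd = ml_energy(hf_engine_dimer, pd)
    assert bd["E_non_add"] == 0.0


def test_ml_energy_partition_sums_to_full_energy(purified_dimer,
                                                 hf_engine_dimer,
                                                 water_dimer):
    """The block decomposition is algebraic: any partition re-sums exactly."""
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    bd = ml_energy(eng, pd)
    ref = eng.energy(purified_dimer.D_alpha, purified_dimer.D_beta)
    assert bd["total"] == pytest.approx(ref, abs=1e-9)


def test_umldft_full_active_energy_matches_uks(water_cation,
                                               pbe0_engine_water_cation):
    eng = pbe0_engine_water_cation
    pur, pd, space = _prep(water_cation, eng, [0, 1, 2])
    bd = ml_energy(eng, pd)
    ref = eng.energy(pur.D_alpha, pur.D_beta)
    assert bd["total"] == pytest.approx(ref, abs=1e-8)


# -- active-space SCF ---------------------------------------------------------

def test_uml_scf_full_active_matches_full_uhf(water_cation,
                                              hf_engine_water_cation):
    eng = hf_engine_water_cation
    pur, pd, space = _prep(water_cation, eng, [0, 1, 2])
    fr = frozen_inactive_terms(eng, pd)
    ml = run_uml_scf(eng, pd, space, fr)
    full = run_scf(eng, D0=(pur.D_alpha, pur.D_beta))
    assert ml.energy == pytest.approx(full.energy, abs=1e-8)
    ml.partitioned.validate()


def test_uml_scf_isolated_he_pair():
    """Active He 50 Å from an inactive He: active energy ~ isolated atom."""
    pair = AtomicSystem(atoms=[Atom("He", 2, (0, 0, 0)),
                               Atom("He", 2, (0, 0, 50.0))],
                        basis_label_per_atom=["6-31g", "6-31g"])
    he = AtomicSystem(atoms=[Atom("He", 2, (0, 0, 0))],
                      basis_label_per_atom=["6-31g"])
    eng = SCFEngine(pair, functional("hf"))
    pur, pd, space = _prep(pair, eng, [0])
    ml = run_uml_scf(eng, pd, space)
    e_iso = run_scf(SCFEngine(he, functional("hf"))).energy
    assert ml.energy_breakdown["E_A"] == pytest.approx(e_iso, abs=1e-6)


def test_uml_scf_zero_iterations_returns_input_state(purified_dimer,
                                                     hf_engine_dimer,
                                                     water_dimer):
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, space = partition_densities(purified_dimer, part, eng.basis)
    fr = frozen_inactive_terms(eng, pd)
    res = run_uml_scf(eng, pd, space, fr, max_iter=0)
    assert np.array_equal(res.partitioned.D_A_alpha, pd.D_A_alpha)
    assert res.energy == pytest.approx(ml_energy(eng, pd, fr)["total"],
                                       abs=1e-12)


def test_uml_scf_keeps_frozen_terms_and_inactive_block(purified_dimer,
                                                       hf_engine_dimer,
                                                       water_dimer):
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, space = partition_densities(purified_dimer, part, eng.basis)
    fr = frozen_inactive_terms(eng, pd)
    res = run_uml_scf(eng, pd, space, fr)
    assert len(set(res.frozen_hash_iterations)) == 1
    assert np.array_equal(res.partitioned.D_B_alpha, pd.D_B_alpha)
    res.partitioned.validate()


def test_variational_bound_larger_active_space(purified_dimer,
                                               hf_engine_dimer, water_dimer):
    eng = hf_engine_dimer
    energies = {}
    for label, active in (("small", [0, 1, 2]), ("large", range(6))):
        part = define_partition(water_dimer, active)
        pd, space = partition_densities(purified_dimer, part, eng.basis)
        res = run_uml_scf(eng, pd, space)
        energies[label] = res.energy
    assert energies["large"] <= energies["small"] + 1e-10


def test_inactive_occupied_rotation_leaves_energy_invariant(
        purified_dimer, hf_engine_dimer, water_dimer):
    """D_B is a projector: any unitary mixing of inactive occupied orbitals
    reassembles the same block, so energy and Fock are invariant."""
    eng = hf_engine_dimer
    part = define_partition(water_dimer, [0, 1, 2])
    pd, _ = partition_densities(purified_dimer, part, eng.basis)
    w, V = np.linalg.eigh(pd.S)
    Shalf = (V * np.sqrt(w)) @ V.T
    Sinvh = (V / np.sqrt(w)) @ V.T
    Ap = Shalf @ pd.D_B_alpha @ Shalf
    ev, U = np.linalg.eigh(0.5 * (Ap + Ap.T))
    occ = U[:, ev > 0.5]
    rng = np.random.default_rng(3)
    Q, _ = np.linalg.qr(rng.normal(size=(occ.shape[1], occ.shape[1])))
    C_rot = Sinvh @ (occ @ Q)
    DB_rot = C_rot @ C_rot.T
    pd_rot = PartitionedDensity(
        D_A_alpha=pd.D_A_alpha, D_A_beta=pd.D_A_beta,
        D_B_alpha=DB_rot, D_B_beta=pd.D_B_beta, S=pd.S,
    )
    e1 = ml_energy(eng, pd)["total"]
    e2 = ml_energy(eng, pd_rot)["total"]
    assert abs(e1 - e2) <= 1e-10
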