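"""Shared fixtures: small molecular systems and session-scoped engines.

Everything is generated programmatically; engines are session-scoped
because the in-core integral build dominates fixture cost.
"""
import math

import numpy as np
import pytest

from mlscf.initial_density import purify_guess, sad_guess
from mlscf.scf import SCFEngine
from mlscf.system import Atom, AtomicSystem, functional


def water_atoms(ox=0.0, oy=0.0, oz=0.0, r=0.9572, angle_deg=104.52):
    th = math.radians(angle_deg)
    return [
        Atom("O", 8, (ox, oy, oz)),
        Atom("H", 1, (ox + r, oy, oz)),
        Atom("H", 1, (ox + r * math.cos(th), oy + r * math.sin(th), oz)),
    ]


@pytest.fixture(scope="session")
def h_atom():
    return AtomicSystem(atoms=[Atom("H", 1, (0.0, 0.0, 0.0))],
                        multiplicity=2)


@pytest.fixture(scope="session")
def water():
    return AtomicSystem(atoms=water_atoms())


@pytest.fixture(scope="session")
def water_cation():
    return AtomicSystem(atoms=water_atoms(), net_charge=1, multiplicity=2)


@pytest.fixture(scope="session")
def water_dimer_cation():
    """(H2O)2+ doublet — the 2-water radical fixture."""
    atoms = water_atoms() + water_atoms(oz=3.0)
    return AtomicSystem(
        atoms=atoms, net_charge=1, multiplicity=2,
        mol_id=np.array([0, 0, 0, 1, 1, 1]),
        solute_mask=np.array([True] * 3 + [False] * 3),
    )


@pytest.fixture(scope="session")
def water_dimer():
    atoms = water_atoms() + water_atoms(oz=3.0)
    return AtomicSystem(
        atoms=atoms,
        mol_id=np.array([0, 0, 0, 1, 1, 1]),
        solute_mask=np.array([True] * 3 + [False] * 3),
    )


@pytest.fixture(scope="session")
def ten_ao_radical():
    """Water + H2 + H — a 10-AO open-shell fixture for gradient checks."""
    atoms = water_atoms() + [
        Atom("H", 1, (0.0, 0.0, 2.6)),
        Atom("H", 1, (0.74, 0.0, 2.6)),
        Atom("H", 1, (0.0, 2.9, 0.0)),
    ]
    return AtomicSystem(
        atoms=atoms, multiplicity=2,
        mol_id=np.array([0, 0, 0, 1, 1, 2]),
        solute_mask=np.array([True] * 3 + [False] * 3),
    )


@pytest.fixture(scope="session")
def hf_engine_water_cation(water_cation):
    return SCFEngine(water_cation, functional("hf"))


@pytest.fixture(scope="session")
def hf_engine_dimer_cation(water_dimer_cation):
    return SCFEngine(water_dimer_cation, functional("hf"))


@pytest.fixture(scope="session")
def hf_engine_dimer(water_dimer):
    return SCFEngine(water_dimer, functional("hf"))


@pytest.fixture(scope="session")
def pbe0_engine_water_cation(water_cation):
    return SCFEngine(water_cation, functional("pbe0"))


@pytest.fixture(scope="session")
def purified_dimer_cation(water_dimer_cation, hf_engine_dimer_cation):
    guess = sad_guess(water_dimer_cation, hf_engine_dimer_cation)
    return purify_guess(water_dimer_cation, guess,
                        engine=hf_engine_dimer_cation)


@pytest.fixture(scope="session")
def purified_dimer(water_dimer, hf_engine_dimer):
    guess = sad_guess(water_dimer, hf_engine_dimer)
    return purify_guess(water_dimer, guess, engine=hf_engine_dimer)
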