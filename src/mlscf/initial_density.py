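"""Initial densities: SAD guess and the single purifying diagonalization.

The multilevel protocol starts from a superposition of atomic densities
(SAD): spherically averaged unrestricted atomic calculations, cached per
(element, basis) pair, assembled block-diagonally over atoms.  One Fock
build from that guess followed by one diagonalization ("purification")
yields idempotent alpha/beta densities with exact integer occupations —
deliberately a single step, not a converged SCF: it captures the bulk of
interfragment polarization/charge transfer before the density is frozen
into active and inactive blocks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import GROUND_STATE_MULTIPLICITY, SYMBOL_FROM_Z
from .scf import SCFEngine, _new_density, run_scf
from .system import AtomicSystem, Atom, FunctionalSpec

log = logging.getLogger(__name__)

IDEMPOTENCY_TOL = 1e-8


@dataclass
class SpinResolvedDensity:
    """Alpha/beta AO density matrices with their overlap metric."""

    D_alpha: np.ndarray
    D_beta: np.ndarray
    S: np.ndarray
    n_alpha: int
    n_beta: int

    @property
    def D_total(self) -> np.ndarray:
        return self.D_alpha + self.D_beta

    @property
    def D_spin(self) -> np.ndarray:
        """The alpha-beta spin density matrix."""
        return self.D_alpha - self.D_beta

    def traces(self) -> tuple[float, float]:
        return (
            float(np.trace(self.D_alpha @ self.S)),
            float(np.trace(self.D_beta @ self.S)),
        )

    def idempotency_residual(self) -> float:
        r = 0.0
        for D in (self.D_alpha, self.D_beta):
            r = max(r, float(np.abs(D @ self.S @ D - D).max()))
        return r

    def is_idempotent(self, tol: float = IDEMPOTENCY_TOL) -> bool:
        return self.idempotency_residual() <= tol


# -- SAD ---------------------------------------------------------------------

_ATOM_CACHE: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}


def _atomic_densities(symbol: str, basis_label: str):
    """Spherically averaged UHF alpha/beta densities of the free atom."""
    key = (symbol, basis_label)
    if key in _ATOM_CACHE:
        return _ATOM_CACHE[key]
    z = {s: z for z, s in SYMBOL_FROM_Z.items()}[symbol]
    atom_sys = AtomicSystem(
        atoms=[Atom(symbol, z, (0.0, 0.0, 0.0))],
        multiplicity=GROUND_STATE_MULTIPLICITY[z],
        basis_label_per_atom=[basis_label],
    )
    eng = SCFEngine(atom_sys, FunctionalSpec())  # UHF
    res = run_scf(eng, spherical_average=True, conv_grad=1e-7)
    _ATOM_CACHE[key] = (res.Da, res.Db)
    return _ATOM_CACHE[key]


def sad_guess(system: AtomicSystem, engine: SCFEngine | None = None
              ) -> SpinResolvedDensity:
    """Superposition-of-atomic-densities guess (block diagonal over atoms).

    The atomic spin densities are rescaled so the total spin excess matches
    the molecular n_alpha - n_beta: a closed-shell molecule gets a
    spin-averaged guess while a free radical atom keeps its full atomic
    polarization.  The guess is not idempotent.
    """
    engine = engine or SCFEngine(system, FunctionalSpec())
    basis = engine.basis
    nao = basis.nao
    D_avg = np.zeros((nao, nao))
    D_pol = np.zeros((nao, nao))
    for ia, atom in enumerate(system.atoms):
        try:
            Da_at, Db_at = _atomic_densities(
                atom.symbol, system.basis_label_per_atom[ia]
            )
        except KeyError as exc:
            raise KeyError(
                f"no basis '{system.basis_label_per_atom[ia]}' entry for atom "
                f"{ia} ({atom.symbol})"
            ) from exc
        lo, hi = basis.atom_ao_ranges[ia]
        D_avg[lo:hi, lo:hi] += 0.5 * (Da_at + Db_at)
        D_pol[lo:hi, lo:hi] += Da_at - Db_at
    excess = system.n_alpha - system.n_beta
    pol_trace = float(np.trace(D_pol @ engine.S))
    lam = excess / pol_trace if abs(pol_trace) > 1e-8 else 0.0
    Da = D_avg + 0.5 * lam * D_pol
    Db = D_avg - 0.5 * lam * D_pol
    return SpinResolvedDensity(
        D_alpha=Da, D_beta=Db, S=engine.S,
        n_alpha=system.n_alpha, n_beta=system.n_beta,
    )


def purify_guess(
    system: AtomicSystem,
    guess: SpinResolvedDensity,
    functional: FunctionalSpec | None = None,
    engine: SCFEngine | None = None,
    fock_hook=None,
) -> SpinResolvedDensity:
    """One Fock build from the guess + one diagonalization per spin.

    Returns S-idempotent densities with exact integer aufbau traces.  If the
    engine carries a static embedding operator it enters this initial Fock;
    a polarizable layer can be injected through ``fock_hook`` (same contract
    as in :func:`mlscf.scf.run_scf`) — the embedding field then polarizes
    the density *before* partitioning, which is the default behaviour of
    the pipeline (configurable).
    """
    engine = engine or SCFEngine(system, functional or FunctionalSpec())
    if guess.D_alpha.shape != (engine.nao, engine.nao):
        raise ValueError("guess dimensions do not match the AO basis")
    Fa, Fb, _ = engine.fock(guess.D_alpha, guess.D_beta)
    if fock_hook is not None:
        dFa, dFb, *_ = fock_hook(guess.D_alpha, guess.D_beta)
        Fa = Fa + dFa
        Fb = Fb + dFb
    Da, Db, _ = _new_density(
        Fa, Fb, engine.X, system.n_alpha, system.n_beta, False
    )
    out = SpinResolvedDensity(
        D_alpha=Da, D_beta=Db, S=engine.S,
        n_alpha=system.n_alpha, n_beta=system.n_beta,
    )
    resid = out.idempotency_residual()
    if resid > IDEMPOTENCY_TOL:
        raise RuntimeError(
            f"purified density not idempotent (residual {resid:.2e}); "
            "overlap may be near-singular"
        )
    return out
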