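"""Multilevel unrestricted SCF: frozen inactive terms, ML Fock and energy,
and energy minimization in the active orbital space only.

The energy of the partitioned system is assembled as

    E = E_A + E_B + E_int + E_non-add + E_nn

with E_A / E_B the pure one- and two-electron energies of the active /
inactive blocks (each including its own exchange-correlation), E_int the
Coulomb + scaled-exact-exchange coupling (the Tr D_A G(D_B) = Tr D_B G(D_A)
symmetry is used exactly once, so the coupling is counted once), and the
nonadditive piece E_xc[rho_A + rho_B] - E_xc[rho_A] - E_xc[rho_B], which
vanishes identically for pure HF.  All nuclear-attraction energy rides in
the one-electron term of the block that owns the density, and the full
nuclear repulsion is booked as a separate constant — the split of nuclear
cross terms between E_B and E_int is bookkeeping; the total is the contract.

The Fock matrix is the derivative of that energy with respect to the active
spin density: F^s = h + 2e_A^s(D_A) + 2e_B^s + 2e_non-add^s, where 2e_B^s
(Coulomb + scaled exchange of the frozen block) is computed once before the
SCF starts and never changes.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .initial_density import SpinResolvedDensity
from .partition import ActiveOrbitalSpace, PartitionedDensity
from .scf import SCFEngine, _DIIS

log = logging.getLogger(__name__)


def _mat_hash(*mats) -> str:
    h = hashlib.sha256()
    for m in mats:
        h.update(np.ascontiguousarray(m).tobytes())
    return h.hexdigest()


@dataclass
class FrozenInactiveTerms:
    """One-time contributions of the frozen inactive density.

    ``twoe_B_*`` enter every Fock build unchanged; ``E_B_const`` collects
    the inactive-only energy plus the constant nuclear repulsion.  The
    inactive densities are kept for the shared-grid nonadditive xc terms.
    """

    twoe_B_alpha: np.ndarray
    twoe_B_beta: np.ndarray
    E_B_const: float
    E_B_electronic: float
    exc_B: float
    D_B_alpha: np.ndarray
    D_B_beta: np.ndarray
    content_hash: str = ""

    def __post_init__(self):
        if not self.content_hash:
            self.content_hash = _mat_hash(self.twoe_B_alpha, self.twoe_B_beta)


@dataclass
class MLFockPair:
    F_alpha: np.ndarray
    F_beta: np.ndarray
    energy_breakdown: dict


def frozen_inactive_terms(
    engine: SCFEngine, partitioned: PartitionedDensity
) -> FrozenInactiveTerms:
    """Protocol step 4: constant energy and one-electron terms of block B."""
    cx = engine.spec.c_x
    DBa, DBb = partitioned.D_B_alpha, partitioned.D_B_beta
    DB = DBa + DBb
    J_B = engine.coulomb(DB)
    twoe_a = J_B.copy()
    twoe_b = J_B.copy()
    if cx != 0.0:
        twoe_a -= cx * engine.exchange(DBa)
        twoe_b -= cx * engine.exchange(DBb)
    e_b = float(np.einsum("mn,mn->", DB, engine.h_core))
    e_b += 0.5 * float(np.einsum("mn,mn->", DB, J_B))
    if cx != 0.0:
        e_b -= 0.5 * cx * (
            float(np.einsum("mn,mn->", DBa, engine.exchange(DBa)))
            + float(np.einsum("mn,mn->", DBb, engine.exchange(DBb)))
        )
    exc_B = 0.0
    if not engine.xc.is_null:
        exc_B = engine.xc_energy_potential(DBa, DBb)[0]
        e_b += exc_B
    return FrozenInactiveTerms(
        twoe_B_alpha=twoe_a, twoe_B_beta=twoe_b,
        E_B_const=e_b + engine.E_nn, E_B_electronic=e_b, exc_B=exc_B,
        D_B_alpha=DBa.copy(), D_B_beta=DBb.copy(),
    )


def ml_energy(
    engine: SCFEngine,
    partitioned: PartitionedDensity,
    frozen: FrozenInactiveTerms | None = None,
    exc_total: float | None = None,
) -> dict:
    """Energy breakdown E_A / E_B / E_int / E_non-add of a partition.

    Reduces exactly to the full unrestricted energy expression: the blocks
    are re-assembled algebraically, not approximated.  When the partition
    carries atom-level region info, each block owns its electrons'
    attraction to its own nuclei and its own nuclear repulsion, and all
    cross pieces (including A-B nuclear repulsion) sit in E_int, so E_A of
    a well-separated fragment approaches its isolated-fragment energy;
    "E_nn" is then informational.  Without region info everything
    one-electron rides in the block owning the density and E_nn is a
    separate constant.  Either way the total is exact.
    """
    cx = engine.spec.c_x
    DAa, DAb = partitioned.D_A_alpha, partitioned.D_A_beta
    DBa, DBb = partitioned.D_B_alpha, partitioned.D_B_beta
    DA, DB = DAa + DAb, DBa + DBb
    J_A = engine.coulomb(DA)
    # 2e_B already holds J(D_B) - cx K(D_B^s); reuse it when available
    e_A = float(np.einsum("mn,mn->", DA, engine.h_core))
    e_A += 0.5 * float(np.einsum("mn,mn->", DA, J_A))
    exc_A = exc_B = exc_tot = 0.0
    if cx != 0.0:
        e_A -= 0.5 * cx * (
            float(np.einsum("mn,mn->", DAa, engine.exchange(DAa)))
            + float(np.einsum("mn,mn->", DAb, engine.exchange(DAb)))
        )
    if not engine.xc.is_null:
        exc_A = engine.xc_energy_potential(DAa, DAb)[0]
        e_A += exc_A
    if frozen is not None:
        e_B = frozen.E_B_electronic
        exc_B = frozen.exc_B
        # E_int via the frozen 2e_B operator: Tr D_A (J_B - cx K_B) uses the
        # Tr D_A G(D_B) = Tr D_B G(D_A) symmetry exactly once.
        e_int = float(np.einsum("mn,mn->", DAa, frozen.twoe_B_alpha))
        e_int += float(np.einsum("mn,mn->", DAb, frozen.twoe_B_beta))
    else:
        JB = engine.coulomb(DB)
        e_B = float(np.einsum("mn,mn->", DB, engine.h_core))
        e_B += 0.5 * float(np.einsum("mn,mn->", DB, JB))
        if cx != 0.0:
            e_B -= 0.5 * cx * (
                float(np.einsum("mn,mn->", DBa, engine.exchange(DBa)))
                + float(np.einsum("mn,mn->", DBb, engine.exchange(DBb)))
            )
        if not engine.xc.is_null:
            exc_B = engine.xc_energy_potential(DBa, DBb)[0]
            e_B += exc_B
        e_int = float(np.einsum("mn,mn->", DA, JB))
        if cx != 0.0:
            e_int -= cx * (
                float(np.einsum("mn,mn->", DAa, engine.exchange(DBa)))
                + float(np.einsum("mn,mn->", DAb, engine.exchange(DBb)))
            )
    e_nonadd = 0.0
    if not engine.xc.is_null:
        exc_tot = (
            exc_total
            if exc_total is not None
            else engine.xc_energy_potential(DAa + DBa, DAb + DBb)[0]
        )
        e_nonadd = exc_tot - exc_A - exc_B
    total = e_A + e_B + e_int + e_nonadd + engine.E_nn
    part = partitioned.partition
    if part is not None and part.inactive_atoms:
        # refine the bookkeeping: cross nuclear attraction and the A-B
        # nuclear repulsion belong to the coupling; each block keeps its
        # own nuclear repulsion.  The total is unchanged.
        act = sorted(part.active_atoms)
        inact = sorted(part.inactive_atoms)
        v_A = engine.nuclear_attraction_subset(act)
        v_B = engine.nuclear_attraction_subset(inact)
        cross_a = float(np.einsum("mn,mn->", DA, v_B))
        cross_b = float(np.einsum("mn,mn->", DB, v_A))
        e_nn_ab = engine.nuclear_repulsion_subsets(act, inact)
        e_A = e_A - cross_a + _self_repulsion(engine, act)
        e_B = e_B - cross_b + _self_repulsion(engine, inact)
        e_int = e_int + cross_a + cross_b + e_nn_ab
    return {
        "E_A": e_A, "E_B": e_B, "E_int": e_int, "E_non_add": e_nonadd,
        "E_nn": engine.E_nn, "E_xc_A": exc_A, "E_xc_B": exc_B,
        "total": total,
    }


def _self_repulsion(engine, atoms):
    e = 0.0
    atoms = list(atoms)
    for ii, i in enumerate(atoms):
        for j in atoms[:ii]:
            e += engine.nuclear_repulsion_subsets([i], [j])
    return e


def build_ml_fock(
    engine: SCFEngine,
    D_A_alpha: np.ndarray,
    D_A_beta: np.ndarray,
    frozen: FrozenInactiveTerms,
    partition=None,
) -> MLFockPair:
    """F^s = h + 2e_A^s(D_A) + 2e_B^s + 2e_non-add^s (and energy breakdown)."""
    cx = engine.spec.c_x
    DA = D_A_alpha + D_A_beta
    J_A = engine.coulomb(DA)
    Fa = engine.h_core + J_A + frozen.twoe_B_alpha
    Fb = engine.h_core + J_A + frozen.twoe_B_beta
    if cx != 0.0:
        Fa = Fa - cx * engine.exchange(D_A_alpha)
        Fb = Fb - cx * engine.exchange(D_A_beta)
    exc_tot = None
    if not engine.xc.is_null:
        # nonadditive xc on the shared grid: v_xc[rho_A + rho_B] enters the
        # Fock (v_xc[rho_A] + 2e_non-add in the grouped notation)
        exc_tot, Va_tot, Vb_tot = engine.xc_energy_potential(
            D_A_alpha + frozen.D_B_alpha, D_A_beta + frozen.D_B_beta
        )
        Fa = Fa + Va_tot
        Fb = Fb + Vb_tot
    part = PartitionedDensity(
        D_A_alpha=D_A_alpha, D_A_beta=D_A_beta,
        D_B_alpha=frozen.D_B_alpha, D_B_beta=frozen.D_B_beta, S=engine.S,
        partition=partition,
    )
    breakdown = ml_energy(engine, part, frozen, exc_total=exc_tot)
    return MLFockPair(F_alpha=0.5 * (Fa + Fa.T), F_beta=0.5 * (Fb + Fb.T),
                      energy_breakdown=breakdown)


@dataclass
class MLSCFResult:
    converged: bool
    energy: float
    energy_breakdown: dict
    partitioned: PartitionedDensity
    orbital_space: ActiveOrbitalSpace
    n_iter: int
    history: list = field(default_factory=list)
    frozen_hash_iterations: list = field(default_factory=list)
    embedding: dict = field(default_factory=dict)


class MLSCFConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def run_uml_scf(
    engine: SCFEngine,
    partitioned: PartitionedDensity,
    orbital_space: ActiveOrbitalSpace,
    frozen: FrozenInactiveTerms | None = None,
    max_iter: int = 100,
    conv_energy: float = 1e-9,
    conv_grad: float = 1e-6,
    diis_size: int = 8,
    fock_hook=None,
) -> MLSCFResult:
    """Protocol step 5: minimize the multilevel energy over the active MOs.

    Only the active occupied/virtual coefficients move; the inactive blocks
    are bitwise untouched.  ``fock_hook(Da_tot, Db_tot)`` (same contract as
    in :func:`mlscf.scf.run_scf`) injects a density-dependent embedding
    operator, re-evaluated on the *total* density each cycle.
    """
    if frozen is None:
        frozen = frozen_inactive_terms(engine, partitioned)
    S = engine.S
    DBa, DBb = frozen.D_B_alpha, frozen.D_B_beta
    spaces = {}
    for spin in ("alpha", "beta"):
        C_occ, C_virt = orbital_space.spin(spin)
        spaces[spin] = np.hstack([C_occ, C_virt])
    n_occ = {"alpha": orbital_space.n_occ[0], "beta": orbital_space.n_occ[1]}
    DA = {"alpha": partitioned.D_A_alpha.copy(),
          "beta": partitioned.D_A_beta.copy()}
    diis = _DIIS(diis_size)
    history = []
    frozen_hashes = []
    e_prev = None
    emb_info = {}
    it = 0
    C_occ_new = {
        "alpha": orbital_space.C_occ_alpha, "beta": orbital_space.C_occ_beta
    }
    for it in range(1, max_iter + 1):
        fock = build_ml_fock(engine, DA["alpha"], DA["beta"], frozen,
                             partition=partitioned.partition)
        e_extra = 0.0
        if fock_hook is not None:
            dFa, dFb, e_extra, emb_info = _apply_hook(
                fock_hook, DA["alpha"] + DBa, DA["beta"] + DBb
            )
            fock = MLFockPair(
                F_alpha=fock.F_alpha + dFa, F_beta=fock.F_beta + dFb,
                energy_breakdown=fock.energy_breakdown,
            )
        frozen_hashes.append(frozen.content_hash)
        e_tot = fock.energy_breakdown["total"] + e_extra
        # projected gradient and DIIS in the active orthonormal MO basis
        F_act = {}
        D_act = {}
        grad = 0.0
        for spin, F in (("alpha", fock.F_alpha), ("beta", fock.F_beta)):
            C = spaces[spin]
            F_act[spin] = C.T @ F @ C
            D_act[spin] = C.T @ S @ DA[spin] @ S @ C
            comm = F_act[spin] @ D_act[spin] - D_act[spin] @ F_act[spin]
            if comm.size:
                grad = max(grad, float(np.abs(comm).max()))
        history.append({"iter": it, "energy": e_tot, "grad": grad})
        de = np.inf if e_prev is None else abs(e_tot - e_prev)
        if grad < conv_grad and de < conv_energy:
            break
        e_prev = e_tot
        na, nb = F_act["alpha"].shape[0], F_act["beta"].shape[0]
        err = np.concatenate([
            (F_act["alpha"] @ D_act["alpha"]
             - D_act["alpha"] @ F_act["alpha"]).ravel(),
            (F_act["beta"] @ D_act["beta"]
             - D_act["beta"] @ F_act["beta"]).ravel(),
        ])
        Fstack = np.concatenate(
            [F_act["alpha"].ravel(), F_act["beta"].ravel()]
        )
        diis.push(Fstack, err)
        Fext = diis.extrapolate()
        Fa_x = Fext[: na * na].reshape(na, na)
        Fb_x = Fext[na * na :].reshape(nb, nb)
        for spin, Fx in (("alpha", Fa_x), ("beta", Fb_x)):
            nocc = n_occ[spin]
            if nocc == 0 or Fx.shape[0] == 0:
                continue
            _, U = np.linalg.eigh(0.5 * (Fx + Fx.T))
            C_new = spaces[spin] @ U[:, :nocc]
            C_occ_new[spin] = C_new
            DA[spin] = C_new @ C_new.T
    else:
        if max_iter > 0:
            raise MLSCFConvergenceError(
                f"multilevel SCF not converged in {max_iter} iterations "
                f"(last grad {history[-1]['grad']:.2e})",
                history,
            )
    if max_iter == 0:
        fock = build_ml_fock(engine, DA["alpha"], DA["beta"], frozen,
                             partition=partitioned.partition)
        e_extra = 0.0
        if fock_hook is not None:
            _, _, e_extra, emb_info = _apply_hook(
                fock_hook, DA["alpha"] + DBa, DA["beta"] + DBb
            )
        history.append(
            {"iter": 0, "energy": fock.energy_breakdown["total"] + e_extra,
             "grad": np.nan}
        )
        it = 0
    out_part = PartitionedDensity(
        D_A_alpha=DA["alpha"], D_A_beta=DA["beta"],
        D_B_alpha=DBa, D_B_beta=DBb, S=S, partition=partitioned.partition,
    )
    out_space = ActiveOrbitalSpace(
        C_occ_alpha=C_occ_new["alpha"], C_occ_beta=C_occ_new["beta"],
        C_virt_alpha=orbital_space.C_virt_alpha,
        C_virt_beta=orbital_space.C_virt_beta,
    )
    breakdown = dict(fock.energy_breakdown)
    if emb_info:
        breakdown["E_embedding"] = history[-1]["energy"] - breakdown["total"]
    return MLSCFResult(
        converged=True,
        energy=history[-1]["energy"],
        energy_breakdown=breakdown,
        partitioned=out_part,
        orbital_space=out_space,
        n_iter=it,
        history=history,
        frozen_hash_iterations=frozen_hashes,
        embedding=emb_info,
    )


def _apply_hook(hook, Da_tot, Db_tot):
    out = hook(Da_tot, Db_tot)
    if len(out) == 4:
        return out
    dFa, dFb, e_extra = out
    return dFa, dFb, e_extra, {}
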