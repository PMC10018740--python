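"""Density-matrix partitioning into active and inactive blocks.

Each idempotent spin density is split by a *partial limited pivoted Cholesky
decomposition* with pivots restricted to AOs on the active atoms: expressed
in the symmetrically orthogonalized basis D' = S^{1/2} D S^{1/2}, the spin
density is an ordinary orthogonal projector, and pivoted Cholesky of a
projector is Gram-Schmidt on its columns — every extracted column is an
orthonormal occupied orbital localized on the pivot AOs, and the residual
remains a projector.  Consequently the active block D_A = L L^T and the
remainder D_B = D - D_A are *exactly* S-idempotent, mutually S-orthogonal,
and carry integer electron counts; these invariants are re-checked
numerically on every partition.

The active virtual space is spanned by projected atomic orbitals (PAOs):
active-atom AOs with all occupied components projected out, Löwdin
orthonormalized with linear dependencies dropped.  A pivoted-Cholesky
factorization of the virtual projector is available as an alternative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import BasisSet
from .initial_density import SpinResolvedDensity
from .system import RegionPartition

DEFAULT_TAU = 0.1
DEFAULT_LINDEP = 1e-8
_IDEMPOTENT_INPUT_TOL = 1e-6


@dataclass
class PartitionedDensity:
    """Active/inactive alpha and beta density blocks (full AO dimension)."""

    D_A_alpha: np.ndarray
    D_A_beta: np.ndarray
    D_B_alpha: np.ndarray
    D_B_beta: np.ndarray
    S: np.ndarray
    # atom-level region bookkeeping (RegionPartition); lets the energy
    # decomposition assign nuclear terms to their owning blocks
    partition: object = None

    def spin_blocks(self, spin: str):
        if spin == "alpha":
            return self.D_A_alpha, self.D_B_alpha
        return self.D_A_beta, self.D_B_beta

    @property
    def D_A_total(self) -> np.ndarray:
        return self.D_A_alpha + self.D_A_beta

    @property
    def D_B_total(self) -> np.ndarray:
        return self.D_B_alpha + self.D_B_beta

    def traces(self) -> dict:
        S = self.S
        return {
            k: float(np.trace(getattr(self, f"D_{k}") @ S))
            for k in ("A_alpha", "A_beta", "B_alpha", "B_beta")
        }

    def validate(self, full: SpinResolvedDensity | None = None,
                 recon_tol: float = 1e-10, idem_tol: float = 1e-8,
                 orth_tol: float = 1e-10, trace_tol: float = 1e-8):
        """Assert the partition invariants; raises AssertionError on failure."""
        S = self.S
        for spin in ("alpha", "beta"):
            DA, DB = self.spin_blocks(spin)
            for blk in (DA, DB):
                assert np.abs(blk @ S @ blk - blk).max() <= idem_tol, (
                    f"{spin} block not S-idempotent"
                )
            assert abs(np.trace(DA @ S @ DB @ S)) <= orth_tol, (
                f"{spin} active/inactive blocks not mutually orthogonal"
            )
            for blk in (DA, DB):
                t = float(np.trace(blk @ S))
                assert abs(t - round(t)) <= trace_tol, (
                    f"{spin} block trace {t} not an integer"
                )
            if full is not None:
                ref = full.D_alpha if spin == "alpha" else full.D_beta
                assert np.abs(DA + DB - ref).max() <= recon_tol, (
                    f"{spin} blocks do not reconstruct the full density"
                )


@dataclass
class ActiveOrbitalSpace:
    """Cholesky occupied orbitals and PAO virtuals spanning the active space."""

    C_occ_alpha: np.ndarray
    C_occ_beta: np.ndarray
    C_virt_alpha: np.ndarray
    C_virt_beta: np.ndarray

    @property
    def n_occ(self) -> tuple[int, int]:
        return self.C_occ_alpha.shape[1], self.C_occ_beta.shape[1]

    @property
    def n_virt(self) -> tuple[int, int]:
        return self.C_virt_alpha.shape[1], self.C_virt_beta.shape[1]

    def spin(self, spin: str):
        if spin == "alpha":
            return self.C_occ_alpha, self.C_virt_alpha
        return self.C_occ_beta, self.C_virt_beta


def _sqrt_overlap(S: np.ndarray):
    w, V = np.linalg.eigh(S)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("overlap matrix not positive definite")
    return (V * np.sqrt(w)) @ V.T, (V / np.sqrt(w)) @ V.T


def partial_cholesky_occupied(
    D_sigma: np.ndarray,
    S: np.ndarray,
    active_aos,
    tau: float = DEFAULT_TAU,
) -> np.ndarray:
    """Occupied Cholesky orbitals of one spin density, pivots on active AOs.

    Returns an S-orthonormal coefficient matrix L with L L^T = D_A^sigma.
    The decomposition stops when the largest remaining diagonal element on
    an active AO falls below ``tau``; the resulting column count is the
    active occupation.  Pivot ties break toward the lower AO index.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    active_aos = np.asarray(sorted(active_aos), dtype=int)
    if len(active_aos) == 0:
        raise ValueError("active AO set is empty")
    nao = D_sigma.shape[0]
    resid = np.abs(D_sigma @ S @ D_sigma - D_sigma).max()
    if resid > _IDEMPOTENT_INPUT_TOL:
        raise ValueError(
            f"input density not S-idempotent (residual {resid:.2e})"
        )
    Shalf, Sinvhalf = _sqrt_overlap(S)
    A = Shalf @ D_sigma @ Shalf
    A = 0.5 * (A + A.T)
    cols = []
    for _ in range(nao):
        d_act = np.diag(A)[active_aos]
        k = int(np.argmax(d_act))          # first max -> lowest AO index
        if d_act[k] < tau:
            break
        p = int(active_aos[k])
        col = A[:, p] / np.sqrt(A[p, p])
        cols.append(col)
        A = A - np.outer(col, col)
        A = 0.5 * (A + A.T)
    if not cols:
        return np.zeros((nao, 0))
    Lp = np.stack(cols, axis=1)
    return Sinvhalf @ Lp


def pao_virtuals(
    S: np.ndarray,
    occupied_coeffs: np.ndarray,
    active_aos,
    lindep_tol: float = DEFAULT_LINDEP,
) -> np.ndarray:
    """PAO-derived active virtual orbitals, S-orthonormal and S-orthogonal
    to *all* occupied orbitals (active and inactive).

    ``occupied_coeffs`` must be S-orthonormal columns spanning the whole
    occupied space of one spin.  Column count equals the rank of the
    projected active-AO block at ``lindep_tol`` (Löwdin eigenvalues).
    """
    active_aos = np.asarray(sorted(active_aos), dtype=int)
    nao = S.shape[0]
    C = occupied_coeffs
    proj = np.eye(nao) - C @ (C.T @ S)
    pao = proj[:, active_aos]
    M = pao.T @ S @ pao
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    keep = w > lindep_tol
    if not np.any(keep):
        raise ValueError("no active virtual space: all PAOs linearly "
                         "dependent on the occupied orbitals")
    return pao @ (U[:, keep] / np.sqrt(w[keep]))


def _cholesky_virtuals(D_sigma, S, active_aos, tau):
    """Alternative virtual space: pivoted Cholesky of the virtual projector."""
    Shalf, Sinvhalf = _sqrt_overlap(S)
    P_virt = np.eye(S.shape[0]) - Shalf @ D_sigma @ Shalf
    P_virt = 0.5 * (P_virt + P_virt.T)
    Dv = Sinvhalf @ P_virt @ Sinvhalf
    return partial_cholesky_occupied(Dv, S, active_aos, tau)


def _occupied_span(D_sigma, S, n_occ):
    """S-orthonormal columns spanning the occupied space of a projector."""
    Shalf, Sinvhalf = _sqrt_overlap(S)
    A = Shalf @ D_sigma @ Shalf
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    order = np.argsort(w)[::-1][:n_occ]
    return Sinvhalf @ V[:, order]


def partition_densities(
    full: SpinResolvedDensity,
    partition: RegionPartition,
    basis: BasisSet,
    tau: float = DEFAULT_TAU,
    lindep_tol: float = DEFAULT_LINDEP,
    virtual_method: str = "pao",
) -> tuple[PartitionedDensity, ActiveOrbitalSpace]:
    """Split idempotent alpha/beta densities into active/inactive blocks and
    build the active occupied + virtual orbital space (protocol step 3).

    The Cholesky decomposition runs once per spin; the active occupation per
    spin emerges from ``tau`` restricted to active pivots.
    """
    active_aos = basis.aos_on_atoms(sorted(partition.active_atoms))
    if len(active_aos) == 0:
        raise ValueError("active atoms carry no AOs")
    S = full.S
    blocks = {}
    occ = {}
    virt = {}
    for spin, D, n in (
        ("alpha", full.D_alpha, full.n_alpha),
        ("beta", full.D_beta, full.n_beta),
    ):
        if n == 0 or np.abs(D).max() < 1e-14:
            L = np.zeros((S.shape[0], 0))
        else:
            L = partial_cholesky_occupied(D, S, active_aos, tau=tau)
        DA = L @ L.T
        blocks[spin] = (DA, D - DA)
        occ[spin] = L
        C_all = _occupied_span(D, S, n) if n else np.zeros((S.shape[0], 0))
        if virtual_method == "pao":
            virt[spin] = pao_virtuals(S, C_all, active_aos, lindep_tol)
        elif virtual_method == "cholesky":
            virt[spin] = _cholesky_virtuals(D, S, active_aos, tau)
        else:
            raise ValueError(f"unknown virtual_method '{virtual_method}'")
    pd = PartitionedDensity(
        D_A_alpha=blocks["alpha"][0], D_A_beta=blocks["beta"][0],
        D_B_alpha=blocks["alpha"][1], D_B_beta=blocks["beta"][1],
        S=S, partition=partition,
    )
    pd.validate(full)
    space = ActiveOrbitalSpace(
        C_occ_alpha=occ["alpha"], C_occ_beta=occ["beta"],
        C_virt_alpha=virt["alpha"], C_virt_beta=virt["beta"],
    )
    return pd, space
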