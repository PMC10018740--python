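"""Self-consistent-field engine: Fock builds, energies, full unrestricted SCF.

:class:`SCFEngine` owns the integrals (overlap, kinetic, nuclear attraction,
in-core two-electron tensor), the quadrature grid for DFT functionals, and an
optional static external one-electron potential (fixed-charge embedding).
:func:`run_scf` is the standard full unrestricted HF/KS solver — Roothaan
iterations with DIIS in a canonically orthogonalized basis.  The multilevel
solver in :mod:`mlscf.multilevel` shares the engine primitives but is an
independent minimization over the active orbital space only; the two paths
cross-validate each other in the full-active limit.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import integrals as ints
from .basis import build_basis
from .grid import MolecularGrid
from .system import AtomicSystem, FunctionalSpec
from .xc import get_functional

log = logging.getLogger(__name__)

_GRID_CHUNK = 60000
_AO_CACHE_BYTES = 400e6


class SCFEngine:
    """Integrals + Fock/energy primitives for one system and functional."""

    def __init__(
        self,
        system: AtomicSystem,
        functional: FunctionalSpec | None = None,
        lindep_tol: float = 1e-10,
        external_potential: np.ndarray | None = None,
    ):
        self.system = system
        self.spec = functional or FunctionalSpec()
        self.basis = build_basis(system)
        self.S, self.T = ints.overlap_kinetic(self.basis)
        self.Vnuc = ints.nuclear_attraction(
            self.basis, system.coords_bohr, system.charges
        )
        self.E_nn = ints.nuclear_repulsion(system.coords_bohr, system.charges)
        self.eri = ints.eri_tensor(self.basis)
        self.nao = self.basis.nao
        self.V_ext = (
            np.zeros((self.nao, self.nao))
            if external_potential is None
            else np.asarray(external_potential, float)
        )
        # canonical orthogonalization
        sval, svec = np.linalg.eigh(self.S)
        keep = sval > lindep_tol
        if not np.any(keep):
            raise np.linalg.LinAlgError("overlap matrix is singular")
        if not np.all(keep):
            log.warning(
                "dropping %d near-linearly-dependent AO combinations",
                int((~keep).sum()),
            )
        self.X = svec[:, keep] / np.sqrt(sval[keep])
        self.xc = get_functional(self.spec.exchange_name,
                                 self.spec.correlation_name,
                                 exchange_scale=1.0 - self.spec.c_x)
        self.grid = None
        self._ao_cache = None
        if self.spec.needs_grid:
            self.grid = MolecularGrid(system, level=self.spec.grid_level)
            nel = (1 + 3 * self.xc.needs_gradient)
            if self.grid.n_points * self.nao * nel * 8 < _AO_CACHE_BYTES:
                self._ao_cache = self._eval_ao(self.grid.points)

    # -- primitives ---------------------------------------------------------
    def nuclear_attraction_subset(self, atom_indices) -> np.ndarray:
        """Attraction operator of a subset of nuclei (cached per subset)."""
        key = frozenset(int(i) for i in atom_indices)
        cache = getattr(self, "_vnuc_subset", None)
        if cache is None:
            cache = self._vnuc_subset = {}
        if key not in cache:
            idx = sorted(key)
            cache[key] = ints.nuclear_attraction(
                self.basis, self.system.coords_bohr[idx],
                self.system.charges[idx],
            )
        return cache[key]

    def nuclear_repulsion_subsets(self, atoms_a, atoms_b) -> float:
        """Point-charge repulsion between two disjoint nucleus sets."""
        coords = self.system.coords_bohr
        z = self.system.charges
        e = 0.0
        for i in atoms_a:
            for j in atoms_b:
                e += z[i] * z[j] / np.linalg.norm(coords[i] - coords[j])
        return float(e)

    @property
    def h_core(self) -> np.ndarray:
        """One-electron Hamiltonian including any static embedding operator."""
        return self.T + self.Vnuc + self.V_ext

    def coulomb(self, D: np.ndarray) -> np.ndarray:
        return np.einsum("mnls,ls->mn", self.eri, D, optimize=True)

    def exchange(self, D_sigma: np.ndarray) -> np.ndarray:
        return np.einsum("mlsn,ls->mn", self.eri, D_sigma, optimize=True)

    def _eval_ao(self, points):
        deriv = 1 if self.xc.needs_gradient else 0
        return ints.ao_values(self.basis, points, deriv=deriv)

    def xc_energy_potential(self, Da: np.ndarray, Db: np.ndarray):
        """Quadrature E_xc and potential matrices for the given spin pair.

        Usable with any density pair (full, active-only, inactive-only),
        always on the engine's shared grid — the multilevel nonadditive
        split relies on every piece being integrated on the same grid.
        """
        if self.xc.is_null or self.grid is None:
            z = np.zeros((self.nao, self.nao))
            return 0.0, z, z.copy()
        gga = self.xc.needs_gradient
        exc = 0.0
        Va = np.zeros((self.nao, self.nao))
        Vb = np.zeros((self.nao, self.nao))
        npts = self.grid.n_points
        for start in range(0, npts, _GRID_CHUNK):
            sl = slice(start, min(start + _GRID_CHUNK, npts))
            w = self.grid.weights[sl]
            if self._ao_cache is not None:
                ao = (
                    self._ao_cache[:, sl, :] if gga else self._ao_cache[sl, :]
                )
            else:
                ao = self._eval_ao(self.grid.points[sl])
            if gga:
                phi = ao[0]
                dphi = ao[1:]
                rho = []
                grad = []
                for D in (Da, Db):
                    phiD = phi @ D
                    rho.append(np.einsum("pm,pm->p", phiD, phi))
                    grad.append(
                        2.0 * np.einsum("pm,xpm->xp", phiD, dphi)
                    )
                saa = np.einsum("xp,xp->p", grad[0], grad[0])
                sab = np.einsum("xp,xp->p", grad[0], grad[1])
                sbb = np.einsum("xp,xp->p", grad[1], grad[1])
                res = self.xc.eval(rho[0], rho[1], saa, sab, sbb)
                exc += float(w @ res.e_density)
                for ispin, (vr, other) in enumerate(
                    ((res.vrho[0], 1), (res.vrho[1], 0))
                ):
                    wv = w * vr
                    Vmat = (phi * wv[:, None]).T @ phi
                    vs_ss = res.vsigma[0] if ispin == 0 else res.vsigma[2]
                    wvec = (
                        2.0 * vs_ss * grad[ispin]
                        + res.vsigma[1] * grad[other]
                    ) * w[None, :]
                    half = np.einsum("xp,xpm->pm", wvec, dphi)
                    cross = phi.T @ half
                    Vmat += cross + cross.T
                    if ispin == 0:
                        Va += Vmat
                    else:
                        Vb += Vmat
            else:
                phi = ao
                rho_a = np.einsum("pm,pm->p", phi @ Da, phi)
                rho_b = np.einsum("pm,pm->p", phi @ Db, phi)
                res = self.xc.eval(rho_a, rho_b)
                exc += float(w @ res.e_density)
                Va += (phi * (w * res.vrho[0])[:, None]).T @ phi
                Vb += (phi * (w * res.vrho[1])[:, None]).T @ phi
        return exc, Va, Vb

    def density_on_grid(self, Da, Db):
        """Total alpha/beta densities sampled on the grid (diagnostics)."""
        rho_a = []
        rho_b = []
        npts = self.grid.n_points
        for start in range(0, npts, _GRID_CHUNK):
            sl = slice(start, min(start + _GRID_CHUNK, npts))
            phi = ints.ao_values(self.basis, self.grid.points[sl], deriv=0)
            rho_a.append(np.einsum("pm,pm->p", phi @ Da, phi))
            rho_b.append(np.einsum("pm,pm->p", phi @ Db, phi))
        return np.concatenate(rho_a), np.concatenate(rho_b)

    def fock(self, Da: np.ndarray, Db: np.ndarray):
        """Standard full Fock pair and the E_xc of the input densities."""
        D = Da + Db
        J = self.coulomb(D)
        cx = self.spec.c_x
        Fa = self.h_core + J
        Fb = self.h_core + J.copy()
        if cx != 0.0:
            Fa -= cx * self.exchange(Da)
            Fb -= cx * self.exchange(Db)
        exc = 0.0
        if not self.xc.is_null:
            exc, Va, Vb = self.xc_energy_potential(Da, Db)
            Fa += Va
            Fb += Vb
        return Fa, Fb, exc

    def energy(self, Da: np.ndarray, Db: np.ndarray,
               exc: float | None = None) -> float:
        """Total energy of the spin pair (full, standard expression)."""
        D = Da + Db
        e = float(np.einsum("mn,mn->", D, self.h_core))
        e += 0.5 * float(np.einsum("mn,mn->", D, self.coulomb(D)))
        cx = self.spec.c_x
        if cx != 0.0:
            e -= 0.5 * cx * (
                float(np.einsum("mn,mn->", Da, self.exchange(Da)))
                + float(np.einsum("mn,mn->", Db, self.exchange(Db)))
            )
        if not self.xc.is_null:
            if exc is None:
                exc = self.xc_energy_potential(Da, Db)[0]
            e += exc
        return e + self.E_nn


def aufbau_occupations(eps: np.ndarray, n_el: float,
                       spherical_average: bool = False,
                       degeneracy_tol: float = 1e-8) -> np.ndarray:
    """Occupation vector filling the lowest orbitals.

    With ``spherical_average`` the occupation of a partially filled
    degenerate group is spread equally over the group (fractional), which is
    how the atomic calculations behind the SAD guess stay rotationally
    invariant.  Without it, occupation is integer aufbau; a degeneracy at
    the Fermi level occupies the lowest-index eigenvectors and warns.
    """
    nmo = len(eps)
    f = np.zeros(nmo)
    n_int = int(round(n_el))
    if not spherical_average:
        f[:n_int] = 1.0
        if 0 < n_int < nmo and eps[n_int] - eps[n_int - 1] < degeneracy_tol:
            warnings.warn(
                "degenerate HOMO at the Fermi level; occupying "
                "lowest-index eigenvectors",
                stacklevel=2,
            )
        return f
    # group by degeneracy
    remaining = float(n_el)
    i = 0
    while i < nmo and remaining > 1e-12:
        j = i
        while j + 1 < nmo and eps[j + 1] - eps[i] < degeneracy_tol:
            j += 1
        g = j - i + 1
        fill = min(remaining, g)
        f[i : j + 1] = fill / g
        remaining -= fill
        i = j + 1
    return f


@dataclass
class SCFResult:
    converged: bool
    energy: float
    Da: np.ndarray
    Db: np.ndarray
    Ca: np.ndarray
    Cb: np.ndarray
    eps_a: np.ndarray
    eps_b: np.ndarray
    n_iter: int
    history: list = field(default_factory=list)


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


class _DIIS:
    def __init__(self, size: int = 8):
        self.size = size
        self.focks: list[np.ndarray] = []
        self.errs: list[np.ndarray] = []

    def push(self, F, err):
        self.focks.append(F.copy())
        self.errs.append(err.copy())
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errs.pop(0)

    def extrapolate(self):
        m = len(self.focks)
        if m < 2:
            return self.focks[-1]
        B = -np.ones((m + 1, m + 1))
        B[m, m] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = float(np.vdot(self.errs[i], self.errs[j]))
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            return self.focks[-1]
        return sum(ci * Fi for ci, Fi in zip(c, self.focks))


def run_scf(
    engine: SCFEngine,
    n_alpha: int | None = None,
    n_beta: int | None = None,
    D0: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 150,
    conv_energy: float = 1e-9,
    conv_grad: float = 1e-6,
    diis_size: int = 8,
    spherical_average: bool = False,
    fock_hook=None,
) -> SCFResult:
    """Full unrestricted SCF with DIIS.

    ``fock_hook(Da, Db) -> (dFa, dFb, e_extra)`` lets a caller add a
    density-dependent operator each cycle (the polarizable embedding layer);
    ``e_extra`` is added to the reported total energy.
    """
    na = engine.system.n_alpha if n_alpha is None else n_alpha
    nb = engine.system.n_beta if n_beta is None else n_beta
    X = engine.X
    S = engine.S
    if D0 is None:
        # core-Hamiltonian guess
        Fa = Fb = engine.h_core
        Da, Db, *_ = _new_density(Fa, Fb, X, na, nb, spherical_average)
    else:
        Da, Db = D0
    diis = _DIIS(diis_size)
    e_prev = None
    history = []
    for it in range(1, max_iter + 1):
        Fa, Fb, exc = engine.fock(Da, Db)
        e_extra = 0.0
        if fock_hook is not None:
            dFa, dFb, e_extra, *_ = fock_hook(Da, Db)
            Fa = Fa + dFa
            Fb = Fb + dFb
        e_tot = engine.energy(Da, Db, exc=exc) + e_extra
        err_a = X.T @ (Fa @ Da @ S - S @ Da @ Fa) @ X
        err_b = X.T @ (Fb @ Db @ S - S @ Db @ Fb) @ X
        grad = max(np.abs(err_a).max(), np.abs(err_b).max())
        history.append({"iter": it, "energy": e_tot, "grad": float(grad)})
        de = np.inf if e_prev is None else abs(e_tot - e_prev)
        if grad < conv_grad and de < conv_energy:
            Ca, eps_a = _diagonalize(Fa, X)
            Cb, eps_b = _diagonalize(Fb, X)
            return SCFResult(True, e_tot, Da, Db, Ca, Cb, eps_a, eps_b, it,
                             history)
        e_prev = e_tot
        diis.push(np.concatenate([Fa, Fb]), np.concatenate([err_a, err_b]))
        Fext = diis.extrapolate()
        Fa_x, Fb_x = Fext[: engine.nao], Fext[engine.nao :]
        Da, Db, *_ = _new_density(Fa_x, Fb_x, X, na, nb, spherical_average)
    raise SCFConvergenceError(
        f"SCF not converged in {max_iter} iterations "
        f"(last grad {history[-1]['grad']:.2e})",
        history,
    )


def _diagonalize(F, X):
    eps, C = np.linalg.eigh(X.T @ F @ X)
    return X @ C, eps


def _new_density(Fa, Fb, X, na, nb, spherical_average):
    out = []
    info = []
    for F, n in ((Fa, na), (Fb, nb)):
        C, eps = _diagonalize(F, X)
        f = aufbau_occupations(eps, n, spherical_average=spherical_average)
        D = (C * f[None, :]) @ C.T
        out.append(D)
        info.append((C, eps, f))
    return out[0], out[1], info
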