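"""Classical embedding layers: fixed point charges and fluctuating charges.

The QM region couples to classical sites purely electrostatically:
E_int = sum_i q_i V_i, where V_i is the full QM electrostatic potential
(nuclear + electronic, active and inactive blocks alike) at site i.  Fixed
charges are static; fluctuating charges (FQ) minimize an
electronegativity-equalization quadratic form under per-fragment total
charge constraints and are re-equilibrated against the QM density every
SCF cycle, giving mutual QM/MM polarization.

The FQ interaction kernel is Ohno-damped Coulomb,
J_ij = eta_bar / sqrt(1 + (eta_bar r_ij)^2) with eta_bar the geometric mean
of the two hardnesses (diagonal J_ii = eta_i), the standard choice of the
FQ force-field lineage; the kernel function is swappable.  Parameter sets
(aqueous FQ chi/eta, TIP3P fixed charges) ship in a versioned data file.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.linalg
import yaml

from . import integrals as ints
from .basis import BasisSet
from .constants import ANGSTROM_TO_BOHR
from .initial_density import SpinResolvedDensity
from .system import AtomicSystem

log = logging.getLogger(__name__)


class EmbeddingError(RuntimeError):
    pass


@dataclass
class EmbeddingSite:
    position: np.ndarray          # Å
    element: str = ""
    kind: str = "fixed"           # "fixed" | "fq"
    q: float = 0.0                # fixed charge (e)
    chi: float = 0.0              # electronegativity (a.u.), FQ sites
    eta: float = 0.0              # hardness (a.u.), FQ sites
    fragment: int = 0


@dataclass
class EmbeddingLayer:
    """An ordered collection of classical sites plus per-fragment charges."""

    sites: list[EmbeddingSite]
    fragment_charges: dict = field(default_factory=dict)  # fragment -> Q (e)

    def __post_init__(self):
        for s in self.sites:
            s.position = np.asarray(s.position, float)
            if s.kind == "fq" and s.eta <= 0:
                raise EmbeddingError(
                    f"FQ site in fragment {s.fragment} has non-positive "
                    "hardness"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions_angstrom(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def positions_bohr(self) -> np.ndarray:
        return self.positions_angstrom * ANGSTROM_TO_BOHR

    @property
    def is_fq(self) -> bool:
        return any(s.kind == "fq" for s in self.sites)

    @property
    def fixed_charges(self) -> np.ndarray:
        return np.array([s.q for s in self.sites])

    def fragments(self) -> list[int]:
        return sorted({s.fragment for s in self.sites if s.kind == "fq"})


# -- parameter sets ----------------------------------------------------------


def load_parameter_sets() -> dict:
    text = resources.files("mlscf").joinpath(
        "data/embedding_params.yaml"
    ).read_text()
    return yaml.safe_load(text)


def layer_from_system(
    solvent: AtomicSystem,
    kind: str = "fq",
    parameter_set: str | None = None,
) -> EmbeddingLayer:
    """Build a layer from a tagged solvent system (fragment = molecule)."""
    params = load_parameter_sets()
    if kind == "fq":
        pset = params["fq"][parameter_set or "fq-water"]
    elif kind == "fixed":
        pset = params["fixed"][parameter_set or "tip3p-charges"]
    else:
        raise ValueError(f"unknown embedding kind '{kind}'")
    mol_id = (
        solvent.mol_id
        if solvent.mol_id is not None
        else np.zeros(solvent.n_atoms, dtype=int)
    )
    sites = []
    frag_q = {}
    for ia, atom in enumerate(solvent.atoms):
        frag = int(mol_id[ia])
        if kind == "fq":
            try:
                chi = pset["chi"][atom.symbol]
                eta = pset["eta"][atom.symbol]
            except KeyError as exc:
                raise EmbeddingError(
                    f"FQ parameter set lacks element {atom.symbol}"
                ) from exc
            sites.append(EmbeddingSite(
                position=np.array(atom.position), element=atom.symbol,
                kind="fq", chi=chi, eta=eta, fragment=frag,
            ))
            frag_q.setdefault(frag, 0.0)
        else:
            try:
                q = pset["q"][atom.symbol]
            except KeyError as exc:
                raise EmbeddingError(
                    f"fixed-charge set lacks element {atom.symbol}"
                ) from exc
            sites.append(EmbeddingSite(
                position=np.array(atom.position), element=atom.symbol,
                kind="fixed", q=q, fragment=frag,
            ))
    return EmbeddingLayer(sites=sites, fragment_charges=frag_q)


def layer_from_csv(path, kind: str = "fq",
                   parameter_set: str | None = None) -> EmbeddingLayer:
    """Read sites from a CSV with columns x,y,z,element,fragment (Å)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    atoms = []
    from .system import Atom, Z_FROM_SYMBOL  # local to avoid cycle at import

    mol = []
    for r in rows:
        sym = r["element"].strip().capitalize()
        atoms.append(Atom(sym, Z_FROM_SYMBOL[sym],
                          (float(r["x"]), float(r["y"]), float(r["z"]))))
        mol.append(int(r["fragment"]))
    sysl = AtomicSystem(atoms=atoms, mol_id=np.array(mol),
                        multiplicity=1 if sum(a.Z for a in atoms) % 2 == 0
                        else 2)
    return layer_from_system(sysl, kind=kind, parameter_set=parameter_set)


# -- potentials and energies -------------------------------------------------


def qm_potential_at_sites(
    density: SpinResolvedDensity,
    system: AtomicSystem,
    basis: BasisSet,
    sites_angstrom: np.ndarray,
) -> np.ndarray:
    """Electrostatic potential of the full QM system at classical sites (a.u.).

    V_i = sum_K Z_K/|r_i - R_K| - Tr[(D^a + D^b) v_i]; the density carries
    both active and inactive blocks by construction.  Set
    ``include_nuclear=False`` via :func:`electronic_potential_at_sites` for
    the strict density-only convention.
    """
    return nuclear_potential_at_sites(system, sites_angstrom) + \
        electronic_potential_at_sites(density, basis, sites_angstrom)


def nuclear_potential_at_sites(system: AtomicSystem,
                               sites_angstrom: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(sites_angstrom, float)) * ANGSTROM_TO_BOHR
    coords = system.coords_bohr
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    if d.min() < 1e-6:
        raise EmbeddingError("classical site coincides with a QM nucleus")
    return (system.charges[None, :] / d).sum(axis=1)


def electronic_potential_at_sites(density: SpinResolvedDensity,
                                  basis: BasisSet,
                                  sites_angstrom: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(sites_angstrom, float)) * ANGSTROM_TO_BOHR
    v_ints = ints.point_charge_integrals(basis, pts)
    return -np.einsum("kmn,mn->k", v_ints, density.D_total)


def embedding_interaction_energy(V: np.ndarray, q: np.ndarray) -> float:
    """E_int = sum_i V_i q_i (Hartree; V in a.u., q in e)."""
    V = np.asarray(V, float)
    q = np.asarray(q, float)
    if V.shape != q.shape:
        raise ValueError("potential and charge arrays differ in length")
    return float(V @ q)


def embedding_fock(layer: EmbeddingLayer, q: np.ndarray,
                   basis: BasisSet) -> np.ndarray:
    """One-electron operator of the charge field, identical for both spins."""
    v_ints = ints.point_charge_integrals(basis, layer.positions_bohr)
    return -np.einsum("k,kmn->mn", np.asarray(q, float), v_ints)


# -- the FQ solve ------------------------------------------------------------


def ohno_kernel(layer: EmbeddingLayer) -> np.ndarray:
    """Charge-charge interaction matrix J (a.u.) over the FQ sites."""
    fq_idx = [i for i, s in enumerate(layer.sites) if s.kind == "fq"]
    eta = np.array([layer.sites[i].eta for i in fq_idx])
    pos = layer.positions_bohr[fq_idx]
    n = len(fq_idx)
    J = np.diag(eta)
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(pos[i] - pos[j])
            eta_bar = np.sqrt(eta[i] * eta[j])
            J[i, j] = J[j, i] = eta_bar / np.sqrt(1.0 + (eta_bar * r) ** 2)
    return J


@dataclass
class FQSolution:
    q: np.ndarray                 # charges per FQ site (e)
    lam: np.ndarray               # one multiplier per fragment
    E_pol: float                  # value of the minimized functional (Ha)
    fragments: list

    def stationarity_residual(self, layer, external_potential) -> float:
        J = ohno_kernel(layer)
        chi = np.array([s.chi for s in layer.sites if s.kind == "fq"])
        frs = self.fragments
        fr_of = [s.fragment for s in layer.sites if s.kind == "fq"]
        lam_full = np.array([self.lam[frs.index(f)] for f in fr_of])
        g = J @ self.q + chi + np.asarray(external_potential) + lam_full
        return float(np.abs(g).max())


def solve_fq(layer: EmbeddingLayer,
             external_potential: np.ndarray) -> FQSolution:
    """Equilibrate FQ charges against an external potential (Eq-12-type
    saddle-point solve with exact per-fragment charge conservation)."""
    fq_sites = [s for s in layer.sites if s.kind == "fq"]
    if not fq_sites:
        raise EmbeddingError("layer contains no FQ sites")
    n = len(fq_sites)
    V = np.asarray(external_potential, float)
    if V.shape != (n,):
        raise ValueError(f"expected {n} potential values, got {V.shape}")
    frags = sorted({s.fragment for s in fq_sites})
    m = len(frags)
    J = ohno_kernel(layer)
    chi = np.array([s.chi for s in fq_sites])
    C = np.zeros((m, n))
    for j, s in enumerate(fq_sites):
        C[frags.index(s.fragment), j] = 1.0
    M = np.zeros((n + m, n + m))
    M[:n, :n] = J
    M[:n, n:] = C.T
    M[n:, :n] = C
    rhs = np.zeros(n + m)
    rhs[:n] = -chi - V
    rhs[n:] = [layer.fragment_charges.get(f, 0.0) for f in frags]
    try:
        sol = scipy.linalg.solve(M, rhs, assume_a="sym")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise EmbeddingError(
            f"singular FQ kernel (fragments {frags})"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise EmbeddingError(f"singular FQ kernel (fragments {frags})")
    q = sol[:n]
    lam = sol[n:]
    e_pol = float(chi @ q + 0.5 * q @ J @ q + q @ V)
    return FQSolution(q=q, lam=lam, E_pol=e_pol, fragments=frags)


# -- SCF coupling ------------------------------------------------------------


class EmbeddingCoupler:
    """Produces the per-cycle Fock/energy contribution of a classical layer.

    For a fixed-charge layer the operator is built once; for an FQ layer the
    charges are re-solved against the current QM potential every cycle.
    Use :meth:`hook` as the ``fock_hook`` of the SCF drivers.
    """

    def __init__(self, engine, layer: EmbeddingLayer,
                 include_nuclear: bool = True):
        self.engine = engine
        self.layer = layer
        self.include_nuclear = include_nuclear
        self._v_ints = ints.point_charge_integrals(
            engine.basis, layer.positions_bohr
        )
        self._v_nuc = nuclear_potential_at_sites(
            engine.system, layer.positions_angstrom
        )
        self._static_F = None
        self.last_solution: FQSolution | None = None
        if not layer.is_fq:
            q = layer.fixed_charges
            self._static_F = -np.einsum("k,kmn->mn", q, self._v_ints)

    def potentials(self, D_total: np.ndarray) -> np.ndarray:
        v = -np.einsum("kmn,mn->k", self._v_ints, D_total)
        if self.include_nuclear:
            v = v + self._v_nuc
        return v

    def hook(self, Da_tot: np.ndarray, Db_tot: np.ndarray):
        D = Da_tot + Db_tot
        V = self.potentials(D)
        if self.layer.is_fq:
            sol = solve_fq(self.layer, V)
            self.last_solution = sol
            q = sol.q
            F = -np.einsum("k,kmn->mn", q, self._v_ints)
            # total embedding energy: coupling + internal FQ quadratic form
            e = float(sol.E_pol)
            info = {"q": q, "lambda": sol.lam, "E_pol": sol.E_pol}
        else:
            q = self.layer.fixed_charges
            F = self._static_F
            e = embedding_interaction_energy(V, q)
            info = {"q": q}
        return F, F, e, info
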