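"""Molecular systems, QM region partitions and functional specifications.

Geometry is stored in Å (the external unit everywhere in this package);
conversion to bohr happens exactly once, through
:attr:`AtomicSystem.coords_bohr`, which every electronic-structure module
uses.  XYZ and PDB readers handle single frames and multi-frame files
(repeated XYZ blocks, PDB MODEL records).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    ATOMIC_MASS,
    GROUND_STATE_MULTIPLICITY,
    SYMBOL_FROM_Z,
    Z_FROM_SYMBOL,
)


class GeometryParseError(ValueError):
    """Raised when a geometry file does not parse under the named standard."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    Z: int
    position: tuple[float, float, float]  # Å


# Residue names recognized as water when tagging PDB solvent molecules.
WATER_RESIDUES = {"HOH", "WAT", "SOL", "TIP3", "SPC"}


@dataclass
class AtomicSystem:
    """A QM system: atoms, charge/multiplicity, per-atom basis labels.

    ``mol_id`` groups atoms into molecules (solute/solvent bookkeeping for the
    solvation pipeline); ``solute_mask`` flags solute atoms.  Both are optional
    for plain single-point calculations.
    """

    atoms: list[Atom]
    net_charge: int = 0
    multiplicity: int = 1
    basis_label_per_atom: list[str] = field(default_factory=list)
    mol_id: np.ndarray | None = None
    solute_mask: np.ndarray | None = None

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise ValueError("system must contain at least one atom")
        coords = self.coords_angstrom
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        n_el = self.n_electrons
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        if (self.multiplicity - 1) % 2 != n_el % 2:
            raise ValueError(
                f"multiplicity {self.multiplicity} incompatible with "
                f"{n_el} electrons"
            )
        if not self.basis_label_per_atom:
            self.basis_label_per_atom = ["sto-3g"] * len(self.atoms)
        if len(self.basis_label_per_atom) != len(self.atoms):
            raise ValueError("one basis label per atom required")
        if self.mol_id is not None:
            self.mol_id = np.asarray(self.mol_id, dtype=int)
        if self.solute_mask is not None:
            self.solute_mask = np.asarray(self.solute_mask, dtype=bool)

    # -- derived quantities -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.Z for a in self.atoms], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(sum(a.Z for a in self.atoms)) - self.net_charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def coords_angstrom(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def coords_bohr(self) -> np.ndarray:
        # The single Å -> bohr boundary.
        return self.coords_angstrom * ANGSTROM_TO_BOHR

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[a.Z] for a in self.atoms])

    def center_of_mass(self, indices: Iterable[int] | None = None) -> np.ndarray:
        """Mass-weighted center in Å (optionally of a subset of atoms)."""
        idx = (
            np.arange(self.n_atoms)
            if indices is None
            else np.asarray(list(indices), dtype=int)
        )
        m = self.masses()[idx]
        return m @ self.coords_angstrom[idx] / m.sum()

    def molecules(self) -> list[np.ndarray]:
        """Atom-index groups per molecule (requires mol_id tags)."""
        if self.mol_id is None:
            return [np.arange(self.n_atoms)]
        out = []
        for mid in np.unique(self.mol_id):
            out.append(np.nonzero(self.mol_id == mid)[0])
        return out

    def subset(self, indices: Sequence[int], **overrides) -> "AtomicSystem":
        """New system from a subset of atoms (order preserved)."""
        idx = list(indices)
        kw = dict(
            atoms=[self.atoms[i] for i in idx],
            net_charge=overrides.pop("net_charge", self.net_charge),
            multiplicity=overrides.pop("multiplicity", self.multiplicity),
            basis_label_per_atom=[self.basis_label_per_atom[i] for i in idx],
            mol_id=None if self.mol_id is None else self.mol_id[idx],
            solute_mask=None
            if self.solute_mask is None
            else self.solute_mask[idx],
        )
        kw.update(overrides)
        return AtomicSystem(**kw)

    def with_basis(self, labels) -> "AtomicSystem":
        if isinstance(labels, str):
            labels = [labels] * self.n_atoms
        return replace(self, basis_label_per_atom=list(labels))


@dataclass(frozen=True)
class RegionPartition:
    """Partition of the QM atoms into active and inactive sets.

    ``classical_sites`` indexes into an EmbeddingLayer and is carried for
    bookkeeping; it never overlaps the QM atom sets.
    """

    active_atoms: frozenset
    inactive_atoms: frozenset
    classical_sites: frozenset = frozenset()

    def __post_init__(self):
        if not self.active_atoms:
            raise ValueError("active set must be non-empty")
        if self.active_atoms & self.inactive_atoms:
            raise ValueError("active and inactive sets overlap")

    @staticmethod
    def validate_against(system: AtomicSystem, part: "RegionPartition"):
        allatoms = set(range(system.n_atoms))
        if set(part.active_atoms) | set(part.inactive_atoms) != allatoms:
            raise ValueError("partition does not cover all QM atoms")


@dataclass(frozen=True)
class FunctionalSpec:
    """Exchange-correlation specification.

    ``c_x`` is the fraction of exact (HF) exchange; empty exchange and
    correlation names with c_x=1 is plain unrestricted HF.
    """

    c_x: float = 1.0
    exchange_name: str = ""
    correlation_name: str = ""
    grid_level: int = 2

    def __post_init__(self):
        if not 0.0 <= self.c_x <= 1.0:
            raise ValueError("c_x must lie in [0, 1]")

    @property
    def is_hf(self) -> bool:
        return not self.exchange_name and not self.correlation_name

    @property
    def needs_grid(self) -> bool:
        return not self.is_hf


FUNCTIONAL_PRESETS = {
    "hf": FunctionalSpec(c_x=1.0),
    "svwn": FunctionalSpec(c_x=0.0, exchange_name="slater",
                           correlation_name="vwn5"),
    "pbe": FunctionalSpec(c_x=0.0, exchange_name="pbe",
                          correlation_name="pbe"),
    "pbe0": FunctionalSpec(c_x=0.25, exchange_name="pbe",
                           correlation_name="pbe"),
}


def functional(name_or_spec, grid_level: int | None = None) -> FunctionalSpec:
    """Resolve a preset name (or pass a FunctionalSpec through)."""
    if isinstance(name_or_spec, FunctionalSpec):
        spec = name_or_spec
    else:
        try:
            spec = FUNCTIONAL_PRESETS[str(name_or_spec).lower()]
        except KeyError as exc:
            raise KeyError(
                f"unknown functional '{name_or_spec}'; presets: "
                f"{sorted(FUNCTIONAL_PRESETS)}"
            ) from exc
    if grid_level is not None:
        spec = replace(spec, grid_level=grid_level)
    return spec


# ---------------------------------------------------------------------------
# geometry readers
# ---------------------------------------------------------------------------


def _atom_from_symbol(sym: str, xyz) -> Atom:
    sym = sym.strip().capitalize()
    if sym not in Z_FROM_SYMBOL:
        raise GeometryParseError(f"unknown element symbol '{sym}'")
    return Atom(sym, Z_FROM_SYMBOL[sym], tuple(float(v) for v in xyz))


def _parse_xyz_frames(text: str) -> list[list[Atom]]:
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except (ValueError, IndexError) as exc:
            raise GeometryParseError(
                f"expected atom count at line {i + 1}"
            ) from exc
        if i + 1 + nat >= len(lines) + 1:
            raise GeometryParseError("truncated XYZ frame")
        atoms = []
        for ln in lines[i + 2 : i + 2 + nat]:
            parts = ln.split()
            if len(parts) < 4:
                raise GeometryParseError(f"bad XYZ atom line: '{ln}'")
            atoms.append(_atom_from_symbol(parts[0], parts[1:4]))
        frames.append(atoms)
        i += 2 + nat
    if not frames:
        raise GeometryParseError("empty XYZ file")
    return frames


_PDB_ELEMENT_FIX = re.compile(r"[^A-Za-z]")


def _parse_pdb_frames(text: str):
    frames: list[list[Atom]] = []
    mol_ids: list[list[int]] = []
    solute: list[list[bool]] = []
    cur_atoms: list[Atom] = []
    cur_mid: list[int] = []
    cur_sol: list[bool] = []

    def flush():
        nonlocal cur_atoms, cur_mid, cur_sol
        if cur_atoms:
            frames.append(cur_atoms)
            mol_ids.append(cur_mid)
            solute.append(cur_sol)
        cur_atoms, cur_mid, cur_sol = [], [], []

    for ln in text.splitlines():
        rec = ln[:6].strip()
        if rec in ("ATOM", "HETATM"):
            elem = ln[76:78].strip() if len(ln) >= 77 else ""
            if not elem:
                elem = _PDB_ELEMENT_FIX.sub("", ln[12:16].strip())[:1]
            try:
                xyz = (float(ln[30:38]), float(ln[38:46]), float(ln[46:54]))
            except ValueError as exc:
                raise GeometryParseError(f"bad PDB coordinates: '{ln}'") from exc
            cur_atoms.append(_atom_from_symbol(elem, xyz))
            resname = ln[17:20].strip().upper()
            try:
                resseq = int(ln[22:26])
            except ValueError:
                resseq = len(cur_mid)
            cur_mid.append(resseq)
            cur_sol.append(resname not in WATER_RESIDUES)
        elif rec == "ENDMDL":
            flush()
    flush()
    if not frames:
        raise GeometryParseError("no ATOM/HETATM records found")
    return frames, mol_ids, solute


def load_frames(
    path, fmt: str | None = None, net_charge: int = 0,
    multiplicity: int | None = None, basis=None,
) -> list[AtomicSystem]:
    """Read all frames of an XYZ or PDB file as AtomicSystems."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("xyz", "pdb"):
        raise ValueError(f"unsupported geometry format '{fmt}'")
    text = path.read_text()
    systems = []
    if fmt == "xyz":
        for atoms in _parse_xyz_frames(text):
            systems.append(
                _make_system(atoms, net_charge, multiplicity, basis)
            )
    else:
        frames, mids, sols = _parse_pdb_frames(text)
        for atoms, mid, sol in zip(frames, mids, sols):
            sys_ = _make_system(atoms, net_charge, multiplicity, basis)
            sys_.mol_id = np.asarray(mid, dtype=int)
            sys_.solute_mask = np.asarray(sol, dtype=bool)
            systems.append(sys_)
    return systems


def _make_system(atoms, net_charge, multiplicity, basis) -> AtomicSystem:
    n_el = int(sum(a.Z for a in atoms)) - net_charge
    if multiplicity is None:
        multiplicity = 1 if n_el % 2 == 0 else 2
    labels = None
    if basis is not None:
        labels = [basis] * len(atoms) if isinstance(basis, str) else list(basis)
    return AtomicSystem(
        atoms=list(atoms), net_charge=net_charge, multiplicity=multiplicity,
        basis_label_per_atom=labels or [],
    )


def load_geometry(
    path, fmt: str | None = None, net_charge: int = 0,
    multiplicity: int | None = None, basis=None,
) -> AtomicSystem:
    """Read the first (or only) frame of an XYZ/PDB file."""
    return load_frames(path, fmt, net_charge, multiplicity, basis)[0]


def write_pdb(frames, path, solute_resname: str = "LIG"):
    """Write one or more tagged frames as a (multi-MODEL) PDB file.

    Solvent molecules are written as HOH residues so the solute/water tags
    round-trip through :func:`load_frames`.
    """
    if isinstance(frames, AtomicSystem):
        frames = [frames]
    lines = []
    multi = len(frames) > 1
    for imod, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {imod:4d}")
        mol_id = (
            frame.mol_id
            if frame.mol_id is not None
            else np.zeros(frame.n_atoms, dtype=int)
        )
        solute = (
            frame.solute_mask
            if frame.solute_mask is not None
            else np.ones(frame.n_atoms, dtype=bool)
        )
        for i, atom in enumerate(frame.atoms):
            res = solute_resname if solute[i] else "HOH"
            x, y, z = atom.position
            lines.append(
                f"HETATM{i + 1:5d} {atom.symbol:<4s} {res:<3s} A"
                f"{int(mol_id[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{atom.symbol:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(frames, path, comment: str = ""):
    """Write one or more frames as (multi-frame) XYZ."""
    if isinstance(frames, AtomicSystem):
        frames = [frames]
    blocks = []
    for frame in frames:
        lines = [str(frame.n_atoms), comment]
        for atom in frame.atoms:
            x, y, z = atom.position
            lines.append(f"{atom.symbol:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# partition construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceRule:
    """Select the n closest solvent molecules as active, whole-molecule.

    ``reference`` is the point distances are measured from: "cm" (solute
    center of mass), "no" (midpoint of a configured N-O pair) or an explicit
    Å coordinate.  ``water_point`` picks the solvent atom carrying the
    distance ("O" for the conventional oxygen proxy, "cm" for the solvent
    molecule's own center of mass, "closest" for the nearest atom).
    Ties break toward the lower original atom index.
    """

    n_waters: int
    reference: object = "cm"
    water_point: str = "O"
    no_pair: tuple[int, int] | None = None


def _reference_point(system: AtomicSystem, rule: DistanceRule,
                     solute_idx: np.ndarray) -> np.ndarray:
    if isinstance(rule.reference, (tuple, list, np.ndarray)):
        return np.asarray(rule.reference, float)
    if rule.reference == "cm":
        return system.center_of_mass(solute_idx)
    if rule.reference == "no":
        pair = rule.no_pair
        if pair is None:
            zs = system.charges[solute_idx]
            ns = solute_idx[zs == 7]
            os_ = solute_idx[zs == 8]
            if len(ns) == 0 or len(os_) == 0:
                raise ValueError(
                    "N-O reference requested but no N/O pair found; "
                    "configure no_pair explicitly"
                )
            pair = (int(ns[0]), int(os_[0]))
        c = system.coords_angstrom
        return 0.5 * (c[pair[0]] + c[pair[1]])
    raise ValueError(f"unknown reference '{rule.reference}'")


def solvent_distances(system: AtomicSystem, rule: DistanceRule,
                      solvent_mols: list[np.ndarray],
                      ref: np.ndarray) -> np.ndarray:
    """Distance of each solvent molecule to the reference point (Å)."""
    coords = system.coords_angstrom
    out = np.empty(len(solvent_mols))
    for k, mol in enumerate(solvent_mols):
        if rule.water_point == "O":
            ox = mol[system.charges[mol] == 8]
            pts = coords[ox if len(ox) else mol]
            out[k] = np.linalg.norm(pts - ref, axis=1).min()
        elif rule.water_point == "cm":
            out[k] = np.linalg.norm(system.center_of_mass(mol) - ref)
        elif rule.water_point == "closest":
            out[k] = np.linalg.norm(coords[mol] - ref, axis=1).min()
        else:
            raise ValueError(f"unknown water_point '{rule.water_point}'")
    return out


def define_partition(system: AtomicSystem, active_selection) -> RegionPartition:
    """Build a RegionPartition from explicit indices or a DistanceRule.

    Explicit selections are 0-based atom indices at this API level (the CLI
    config layer accepts 1-based lists and converts).
    """
    allatoms = set(range(system.n_atoms))
    if isinstance(active_selection, DistanceRule):
        if system.mol_id is None or system.solute_mask is None:
            raise ValueError("distance rules require solute/molecule tags")
        solute_idx = np.nonzero(system.solute_mask)[0]
        solvent_mols = [
            m for m in system.molecules() if not system.solute_mask[m[0]]
        ]
        rule = active_selection
        if rule.n_waters > len(solvent_mols):
            raise ValueError(
                f"requested {rule.n_waters} active solvent molecules, "
                f"only {len(solvent_mols)} present"
            )
        ref = _reference_point(system, rule, solute_idx)
        d = solvent_distances(system, rule, solvent_mols, ref)
        # stable sort on (distance, first atom index) => documented tie-break
        first_atom = np.array([m.min() for m in solvent_mols])
        order = np.lexsort((first_atom, d))
        active = set(solute_idx.tolist())
        for k in order[: rule.n_waters]:
            active |= set(solvent_mols[k].tolist())
    else:
        active = set(int(i) for i in active_selection)
        if len(active) != len(list(active_selection)):
            raise ValueError("duplicate indices in active selection")
        if not active <= allatoms:
            raise ValueError("active indices out of range")
    if not active:
        raise ValueError("active set must be non-empty")
    part = RegionPartition(
        active_atoms=frozenset(active),
        inactive_atoms=frozenset(allatoms - active),
    )
    RegionPartition.validate_against(system, part)
    return part
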