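"""Gaussian basis sets: data files, shell construction and AO index maps.

Basis data ship as JSON files under ``mlscf/data`` (one file per basis,
coefficients referring to normalized primitives).  Mixed-basis calculations
are expressed through per-atom basis labels on the
:class:`~mlscf.system.AtomicSystem`, e.g. a radical at one basis and the
surrounding waters at another.

Only s and p shells are supported; the shipped sets (STO-3G, 6-31G) contain
nothing higher.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import pi, sqrt

import numpy as np

_L_FROM_LETTER = {"s": 0, "p": 1}
_MAX_L = 1

# Cartesian component exponents per angular momentum, AO ordering (s; px,py,pz).
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
}


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Normalization constant of a cartesian primitive x^l e^{-a r^2} (l<=1)."""
    return (2.0 * alpha / pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / sqrt(
        _double_factorial(2 * l - 1)
    )


@dataclass
class Shell:
    """A contracted shell on one atom; coefficients carry all norms folded in."""

    l: int
    center: np.ndarray          # bohr
    exps: np.ndarray
    coefs: np.ndarray           # include primitive + contracted normalization
    atom_index: int
    ao_start: int = 0

    @property
    def nao(self) -> int:
        return n_cart(self.l)


_BASIS_CACHE: dict[str, dict] = {}


def load_basis_data(name: str) -> dict:
    """Load a basis JSON by name from the package data directory."""
    key = name.lower()
    if key not in _BASIS_CACHE:
        try:
            text = (
                resources.files("mlscf").joinpath(f"data/{key}.json").read_text()
            )
        except FileNotFoundError as exc:
            raise KeyError(f"unknown basis set '{name}'") from exc
        _BASIS_CACHE[key] = json.loads(text)
    return _BASIS_CACHE[key]


def _contracted_norm(l: int, exps: np.ndarray, coefs: np.ndarray) -> float:
    # Self-overlap of a contracted (l,0,0) cartesian function with primitive
    # norms already folded into `coefs`.
    p = exps[:, None] + exps[None, :]
    s = (pi / p) ** 1.5 * _double_factorial(2 * l - 1) / (2.0 * p) ** l
    total = float(coefs @ s @ coefs)
    return 1.0 / sqrt(total)


def shells_for_atom(
    element: str, basis_name: str, center_bohr: np.ndarray, atom_index: int
) -> list[Shell]:
    try:
        data = load_basis_data(basis_name)
        raw = data["elements"][element]
    except KeyError as exc:
        raise KeyError(
            f"no basis '{basis_name}' entry for element '{element}'"
            f" (atom index {atom_index})"
        ) from exc
    shells = []
    for letter, exps, coefs in raw:
        l = _L_FROM_LETTER[letter]
        if l > _MAX_L:
            raise ValueError("only s and p shells are supported")
        exps = np.asarray(exps, dtype=float)
        coefs = np.asarray(coefs, dtype=float)
        coefs = coefs * np.array([primitive_norm(a, l) for a in exps])
        coefs = coefs * _contracted_norm(l, exps, coefs)
        shells.append(
            Shell(l=l, center=np.asarray(center_bohr, float), exps=exps,
                  coefs=coefs, atom_index=atom_index)
        )
    return shells


@dataclass
class BasisSet:
    """All shells of a molecular system plus AO bookkeeping."""

    shells: list[Shell]
    nao: int
    ao_atom: np.ndarray                  # AO index -> atom index
    atom_ao_ranges: list[tuple[int, int]]  # per atom [start, stop)
    _packed: tuple | None = field(default=None, repr=False)

    def aos_on_atoms(self, atom_indices) -> np.ndarray:
        """Sorted AO indices centered on the given atoms."""
        sel = np.isin(self.ao_atom, np.asarray(list(atom_indices), dtype=int))
        return np.nonzero(sel)[0]

    def packed(self):
        """Flat numpy arrays consumed by the numba integral kernels."""
        if self._packed is None:
            nsh = len(self.shells)
            maxp = max(len(s.exps) for s in self.shells)
            l_arr = np.zeros(nsh, dtype=np.int64)
            np_arr = np.zeros(nsh, dtype=np.int64)
            exp_arr = np.zeros((nsh, maxp))
            coef_arr = np.zeros((nsh, maxp))
            cen_arr = np.zeros((nsh, 3))
            off_arr = np.zeros(nsh, dtype=np.int64)
            for i, s in enumerate(self.shells):
                l_arr[i] = s.l
                np_arr[i] = len(s.exps)
                exp_arr[i, : len(s.exps)] = s.exps
                coef_arr[i, : len(s.coefs)] = s.coefs
                cen_arr[i] = s.center
                off_arr[i] = s.ao_start
            self._packed = (l_arr, np_arr, exp_arr, coef_arr, cen_arr, off_arr)
        return self._packed


def build_basis(system) -> BasisSet:
    """Construct the BasisSet for an AtomicSystem (positions go Å -> bohr here
    via the system's bohr coordinates)."""
    shells: list[Shell] = []
    ao_atom = []
    ranges = []
    nao = 0
    coords = system.coords_bohr
    for ia, atom in enumerate(system.atoms):
        start = nao
        for sh in shells_for_atom(
            atom.symbol, system.basis_label_per_atom[ia], coords[ia], ia
        ):
            sh.ao_start = nao
            nao += sh.nao
            shells.append(sh)
            ao_atom.extend([ia] * sh.nao)
        ranges.append((start, nao))
    return BasisSet(
        shells=shells, nao=nao, ao_atom=np.array(ao_atom, dtype=int),
        atom_ao_ranges=ranges,
    )
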