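"""Isotropic hyperfine coupling constants from the Fermi-contact interaction.

The observable is the alpha-beta spin density at each nucleus,

    rho_X = sum_{mu nu} D^{alpha-beta}_{mu nu} chi_mu(R_X) chi_nu(R_X),

evaluated with the *total* spin density (active plus inactive blocks).  The
isotropic coupling A_X is the Fermi-contact term; its unit chain, written
out step by step:

  1. energy form (SI):  A_E = (mu0/4pi) (8pi/3) g_e mu_B g_X mu_N
                              rho_X / (2<S_z>)  [J]
     with rho_X converted from bohr^-3 to m^-3,
  2. field form:        A_B = A_E / (g_e mu_B)  [T]   (g_e cancels),
  3. reported value:    A_X = 1e4 * A_B  [Gauss].

The free-electron g factor is pinned to the printed EPR-literature value
2.0022319 (see mlscf.constants); the hydrogen-atom closed form — exact 1s
density 1/pi bohr^-3 gives 507.7 G — anchors the prefactor convention, and
the test suite holds the module to it.  <S_z> = (n_alpha - n_beta)/2 of the
total system.  The dipolar tensor vanishes in isotropic media and is
reported as an explicit zero-trace placeholder, not computed.
"""
from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import integrals as ints
from .basis import BasisSet
from .constants import (
    BOHR_METER,
    G_E,
    MU0_OVER_4PI,
    MU_B_SI,
    MU_N_SI,
)
from .initial_density import SpinResolvedDensity
from .system import AtomicSystem

log = logging.getLogger(__name__)

# Tesla per (g_X * rho[bohr^-3] / (2<S_z>)); see the unit chain above.
_PREFACTOR_T = MU0_OVER_4PI * (8.0 * np.pi / 3.0) * MU_N_SI / BOHR_METER ** 3
GAUSS_PER_AU = _PREFACTOR_T * 1e4

DEFAULT_ISOTOPE = {"H": "1H", "C": "13C", "N": "14N", "O": "17O"}


def _load_isotopes() -> dict:
    text = resources.files("mlscf").joinpath("data/isotopes.csv").read_text()
    rows = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    out = {}
    for row in csv.DictReader(rows):
        out[row["isotope"]] = {
            "element": row["element"],
            "spin": float(row["spin"]),
            "g": float(row["g_factor"]),
        }
    return out


ISOTOPES = _load_isotopes()


def spin_density_at_nuclei(
    D_alpha: np.ndarray,
    D_beta: np.ndarray,
    basis: BasisSet,
    nuclei_bohr: np.ndarray,
) -> np.ndarray:
    """rho^{alpha-beta} at each given nuclear position (a.u.^-3)."""
    if D_alpha.shape != D_beta.shape:
        raise ValueError("alpha/beta densities differ in dimension")
    pts = np.atleast_2d(np.asarray(nuclei_bohr, float))
    phi = ints.ao_values(basis, pts, deriv=0)          # (npts, nao)
    Dspin = D_alpha - D_beta
    return np.einsum("pm,mn,pn->p", phi, Dspin, phi)


def hyperfine_constant(
    rho_X: float,
    isotope: str,
    spin_expectation: float,
) -> float:
    """Isotropic hcc in Gauss for one nucleus (Fermi-contact only)."""
    if isotope not in ISOTOPES:
        raise KeyError(
            f"unknown isotope '{isotope}'; available: {sorted(ISOTOPES)}"
        )
    if spin_expectation == 0:
        raise ValueError("spin expectation <S_z> must be non-zero")
    g_x = ISOTOPES[isotope]["g"]
    return GAUSS_PER_AU * g_x * rho_X / (2.0 * spin_expectation)


@dataclass
class HyperfineResult:
    """Per-nucleus spin densities and couplings, plus the constants used."""

    nuclei: list                  # (atom index, element, isotope)
    rho_spin: np.ndarray          # a.u.^-3
    A_iso: np.ndarray             # Gauss
    spin_expectation: float
    A_dip: np.ndarray = None     # zero-trace placeholder, one 3x3 per nucleus
    constants_used: dict = field(default_factory=lambda: {
        "g_e": (G_E, "printed EPR-literature value"),
        "mu_B": (MU_B_SI, "CODATA-2018, J/T"),
        "mu_N": (MU_N_SI, "CODATA-2018, J/T"),
        "gauss_per_au": (GAUSS_PER_AU, "derived prefactor, G per a.u."),
    })

    def __post_init__(self):
        if self.A_dip is None:
            self.A_dip = np.zeros((len(self.nuclei), 3, 3))

    def as_rows(self) -> list[dict]:
        return [
            {
                "atom_index": idx, "element": el, "isotope": iso,
                "rho_spin_au": float(r), "A_iso_gauss": float(a),
            }
            for (idx, el, iso), r, a in zip(
                self.nuclei, self.rho_spin, self.A_iso
            )
        ]


def hyperfine(
    system: AtomicSystem,
    basis: BasisSet,
    density: SpinResolvedDensity,
    nuclei=None,
    isotopes: dict | None = None,
    active_atoms=None,
) -> HyperfineResult:
    """Spin densities and hccs for the requested nuclei.

    ``nuclei`` is a list of atom indices (default: all atoms with a
    tabulated default isotope).  Couplings are conventionally reported for
    active atoms only; requesting an inactive nucleus (when
    ``active_atoms`` is given) warns but still evaluates — the quantity is
    well defined, the restriction is a reporting convention.
    """
    if nuclei is None:
        nuclei = [
            i for i, a in enumerate(system.atoms)
            if a.symbol in DEFAULT_ISOTOPE
        ]
    nuclei = list(nuclei)
    for i in nuclei:
        if not 0 <= i < system.n_atoms:
            raise IndexError(f"nucleus index {i} out of range")
    if active_atoms is not None:
        outside = [i for i in nuclei if i not in set(active_atoms)]
        if outside:
            warnings.warn(
                f"hyperfine requested for inactive atoms {outside}; values "
                "are defined but conventionally reported for active atoms "
                "only",
                stacklevel=2,
            )
    iso_map = dict(DEFAULT_ISOTOPE)
    if isotopes:
        iso_map.update(isotopes)
    labels = []
    for i in nuclei:
        el = system.atoms[i].symbol
        iso = iso_map.get(el) or iso_map.get(i)
        if iso is None or iso not in ISOTOPES:
            raise KeyError(
                f"no isotope tabulated for atom {i} ({el}); "
                f"available: {sorted(ISOTOPES)}"
            )
        labels.append((i, el, iso))
    sz = 0.5 * (density.n_alpha - density.n_beta)
    rho = spin_density_at_nuclei(
        density.D_alpha, density.D_beta, basis,
        system.coords_bohr[nuclei],
    )
    if sz == 0:
        a_iso = np.zeros(len(nuclei))
    else:
        a_iso = np.array([
            hyperfine_constant(r, iso, sz) for (_, _, iso), r
            in zip(labels, rho)
        ])
    return HyperfineResult(
        nuclei=labels, rho_spin=rho, A_iso=a_iso, spin_expectation=sz,
    )
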