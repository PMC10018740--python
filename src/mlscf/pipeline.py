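"""Solvation-snapshot pipeline: droplet carving, layer selection, per-frame
multilevel hcc evaluation and ensemble statistics.

A snapshot is a tagged frame (solute + rigid waters).  For each frame the
pipeline carves a spherical droplet around the solute center of mass,
assigns an inner shell to the QM region and the remainder to a classical
layer (fixed-charge or FQ), picks the n closest waters (by N-O-midpoint or
center-of-mass distance) as the active fragment, runs the multilevel SCF
and evaluates hyperfine couplings and the out-of-plane (pyramidalization)
angle.  Ensemble means carry standard errors se = sigma/sqrt(N_snap) at the
67% confidence level.

The synthetic-snapshot generator stands in for a classical MD sampling
step: rigid waters are rejection-packed around a rigid radical whose
out-of-plane angle is randomly distorted frame to frame, emulating the
pyramidalization spread that dominates the hcc distribution in solution.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .embedding import EmbeddingCoupler, EmbeddingLayer, layer_from_system
from .hyperfine import hyperfine
from .initial_density import SpinResolvedDensity, purify_guess, sad_guess
from .multilevel import frozen_inactive_terms, run_uml_scf
from .partition import DEFAULT_LINDEP, DEFAULT_TAU, partition_densities
from .scf import SCFEngine
from .system import (
    Atom,
    AtomicSystem,
    DistanceRule,
    RegionPartition,
    define_partition,
    functional,
    solvent_distances,
)

log = logging.getLogger(__name__)

# rigid TIP3P-style water geometry (Å)
_WATER_R_OH = 0.9572
_WATER_ANGLE = math.radians(104.52)


def water_template() -> np.ndarray:
    """O, H, H coordinates of a rigid water at the origin (Å)."""
    return np.array([
        [0.0, 0.0, 0.0],
        [_WATER_R_OH, 0.0, 0.0],
        [_WATER_R_OH * math.cos(_WATER_ANGLE),
         _WATER_R_OH * math.sin(_WATER_ANGLE), 0.0],
    ])


def h2no_solute() -> AtomicSystem:
    """Planar aminoxyl radical H2NO* — the smallest nitroxide-like solute.

    Atom order N, O, H, H; the improper quadruple (H, H, N, O) plays the
    role of the C-C-N-O out-of-plane angle of ring nitroxides.
    """
    r_no, r_nh = 1.28, 1.01
    ang = math.radians(120.0)
    atoms = [
        Atom("N", 7, (0.0, 0.0, 0.0)),
        Atom("O", 8, (r_no, 0.0, 0.0)),
        Atom("H", 1, (r_nh * math.cos(ang), r_nh * math.sin(ang), 0.0)),
        Atom("H", 1, (r_nh * math.cos(ang), -r_nh * math.sin(ang), 0.0)),
    ]
    return AtomicSystem(
        atoms=atoms, multiplicity=2,
        mol_id=np.zeros(4, dtype=int),
        solute_mask=np.ones(4, dtype=bool),
    )


H2NO_OOP_QUAD = (2, 3, 0, 1)  # (H, H, N, O)


# ---------------------------------------------------------------------------
# geometry analysis
# ---------------------------------------------------------------------------


def out_of_plane_angle(frame: AtomicSystem, quad) -> float:
    """Out-of-plane angle (degrees) of atom d w.r.t. the a-b-c plane.

    ``quad`` = (a, b, c, d): the flanking pair, the pyramidal center and the
    out-of-plane substituent (C-C-N-O for ring nitroxides).  Returns the
    signed angle between the c-d bond and the a-b-c plane, in (-90, 90];
    positive when d lies on the side of the plane normal (a-c) x (b-c).
    """
    a, b, c, d = (int(i) for i in quad)
    if len({a, b, c, d}) != 4:
        raise ValueError("four distinct atom indices required")
    r = frame.coords_angstrom
    n = np.cross(r[a] - r[c], r[b] - r[c])
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("flanking atoms are collinear with the center")
    v = r[d] - r[c]
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise ValueError("center and out-of-plane atom coincide")
    s = float(np.dot(n, v) / (nn * nv))
    return math.degrees(math.asin(np.clip(s, -1.0, 1.0)))


def ensemble_stats(values) -> "SnapshotEnsemble":
    """Mean, unbiased sigma and se = sigma/sqrt(N) of per-snapshot values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("ensemble statistics require at least 2 snapshots")
    sigma = float(vals.std(ddof=1))
    return SnapshotEnsemble(
        values=vals, mean=float(vals.mean()), sigma=sigma,
        se=sigma / math.sqrt(vals.size), n_snap=int(vals.size),
    )


@dataclass
class SnapshotEnsemble:
    values: np.ndarray
    mean: float
    sigma: float
    se: float
    n_snap: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "mean": self.mean, "sigma": self.sigma, "se": self.se,
            "n_snap": self.n_snap, **self.metadata,
        }


# ---------------------------------------------------------------------------
# droplet / layer selection
# ---------------------------------------------------------------------------


def _require_tags(frame: AtomicSystem):
    if frame.mol_id is None or frame.solute_mask is None:
        raise ValueError("frame lacks solute/molecule tags")


def _solvent_molecules(frame: AtomicSystem):
    return [m for m in frame.molecules() if not frame.solute_mask[m[0]]]


def carve_droplet(frame: AtomicSystem, radius: float,
                  water_point: str = "O") -> AtomicSystem:
    """Spherical droplet around the solute center of mass (solute kept whole;
    a solvent molecule is kept iff its reference atom lies within radius)."""
    _require_tags(frame)
    solute_idx = np.nonzero(frame.solute_mask)[0]
    ref = frame.center_of_mass(solute_idx)
    mols = _solvent_molecules(frame)
    rule = DistanceRule(0, water_point=water_point)
    d = solvent_distances(frame, rule, mols, ref)
    keep = list(solute_idx)
    for mol, dist in zip(mols, d):
        if dist <= radius:
            keep.extend(mol.tolist())
    keep = sorted(keep)
    return frame.subset(keep)


def select_layers(
    droplet: AtomicSystem,
    qm_radius: float,
    n_active: int,
    scheme: str = "NO",
    embedding: str = "fq",
    parameter_set: str | None = None,
    water_point: str = "O",
    no_pair: tuple[int, int] | None = None,
    n_qm: int | None = None,
):
    """Split a droplet into QM (active+inactive) and classical layers.

    Waters whose reference atom lies within ``qm_radius`` of the solute
    center of mass form the QM shell (``n_qm`` instead selects the that many
    closest waters); among them the ``n_active`` closest under the scheme
    ("NO": N-O-bond midpoint, "CM": solute center of mass) join the solute
    in the active region.  Returns (qm_system, partition, layer, info).
    """
    _require_tags(droplet)
    solute_idx = np.nonzero(droplet.solute_mask)[0]
    mols = _solvent_molecules(droplet)
    ref_cm = droplet.center_of_mass(solute_idx)
    rule = DistanceRule(0, water_point=water_point)
    d_cm = solvent_distances(droplet, rule, mols, ref_cm)
    order = np.argsort(d_cm, kind="stable")
    if n_qm is not None:
        qm_mask = np.zeros(len(mols), dtype=bool)
        qm_mask[order[:n_qm]] = True
    else:
        qm_mask = d_cm <= qm_radius
    n_shell = int(qm_mask.sum())
    if n_active > n_shell:
        raise ValueError(
            f"n_active={n_active} exceeds the QM-shell water count {n_shell}"
        )
    qm_atoms = sorted(
        list(solute_idx)
        + [i for k, m in enumerate(mols) if qm_mask[k] for i in m.tolist()]
    )
    mm_atoms = sorted(
        i for k, m in enumerate(mols) if not qm_mask[k] for i in m.tolist()
    )
    qm_system = droplet.subset(qm_atoms)
    if scheme.upper() == "NO":
        sel_rule = DistanceRule(n_active, reference="no",
                                water_point=water_point, no_pair=no_pair)
    elif scheme.upper() == "CM":
        sel_rule = DistanceRule(n_active, reference="cm",
                                water_point=water_point)
    else:
        raise ValueError(f"unknown selection scheme '{scheme}'")
    part = define_partition(qm_system, sel_rule)
    layer = None
    if embedding != "none" and mm_atoms:
        mm_system = droplet.subset(mm_atoms, multiplicity=1, net_charge=0)
        layer = layer_from_system(mm_system, kind=embedding,
                                  parameter_set=parameter_set)
        part = RegionPartition(
            active_atoms=part.active_atoms,
            inactive_atoms=part.inactive_atoms,
            classical_sites=frozenset(range(layer.n_sites)),
        )
    info = {
        "n_qm_waters": n_shell,
        "n_active_waters": n_active,
        "n_classical_waters": len(mols) - n_shell,
        "scheme": scheme.upper(),
    }
    return qm_system, part, layer, info


# ---------------------------------------------------------------------------
# synthetic snapshots
# ---------------------------------------------------------------------------


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _dipole_field(p_vec: np.ndarray, center: np.ndarray,
                  at: np.ndarray) -> np.ndarray:
    """Field of an ideal point dipole p at `center`, evaluated at `at`."""
    r = at - center
    rn = np.linalg.norm(r)
    rhat = r / rn
    return (3.0 * np.dot(p_vec, rhat) * rhat - p_vec) / rn ** 3


def _oriented_rotation(rng, from_dir: np.ndarray, to_dir: np.ndarray,
                       wobble_deg: float) -> np.ndarray:
    """Rotation mapping `from_dir` onto `to_dir` wobbled by a normal
    angular draw, with a uniform random spin about the final axis."""
    d = to_dir / np.linalg.norm(to_dir)
    perp = np.cross(d, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    th = math.radians(rng.normal(0.0, wobble_deg))
    d = math.cos(th) * d + math.sin(th) * perp
    d /= np.linalg.norm(d)
    e1 = np.cross(d, perp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    c1 = math.cos(phi) * e1 + math.sin(phi) * e2
    c2 = -math.sin(phi) * e1 + math.cos(phi) * e2
    # columns = images of the frame (from_dir, its two perpendiculars)
    f = from_dir / np.linalg.norm(from_dir)
    g1 = np.cross(f, [0.0, 0.0, 1.0])
    if np.linalg.norm(g1) < 1e-8:
        g1 = np.cross(f, [0.0, 1.0, 0.0])
    g1 /= np.linalg.norm(g1)
    g2 = np.cross(f, g1)
    A = np.column_stack([f, g1, g2])        # body frame
    B = np.column_stack([d, c1, c2])        # target frame
    return B @ A.T


def _distort_oop(solute: AtomicSystem, quad, angle_deg: float
                 ) -> AtomicSystem:
    """Rotate the out-of-plane atom about the flanking-pair axis through the
    center, changing the improper angle by ~angle_deg."""
    a, b, c, d = quad
    coords = solute.coords_angstrom.copy()
    axis = coords[a] - coords[b]
    axis /= np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
    coords[d] = coords[c] + R @ (coords[d] - coords[c])
    atoms = [
        Atom(at.symbol, at.Z, tuple(coords[i]))
        for i, at in enumerate(solute.atoms)
    ]
    return replace(solute, atoms=atoms)


def generate_synthetic_snapshots(
    seed: int,
    n_frames: int,
    solute: AtomicSystem | None = None,
    n_waters: int = 40,
    box_radius: float = 8.0,
    min_dist: float = 2.4,
    solute_min_dist: float = 2.7,
    oop_sigma_deg: float = 8.0,
    oop_quad=None,
    hbond_wobble_deg: float | None = 30.0,
    max_attempts_per_water: int = 500,
) -> list[AtomicSystem]:
    """Reproducible solute + rigid-water frames inside a sphere.

    Waters are rejection-packed: uniformly random oxygen positions within
    ``box_radius`` of the origin, accepted only if every water-water O-O
    distance is at least ``min_dist`` Å and every O-to-solute-heavy-atom
    distance at least ``solute_min_dist`` Å (the hydration-contact
    distance — close enough for an H-bond, no steric clash).  The
    solute's out-of-plane angle is distorted by a zero-mean normal draw of
    width ``oop_sigma_deg`` each frame.

    Water orientations emulate the orientational order of a hydration
    shell: one O-H bond points toward the solute oxygen (the H-bond
    acceptor of a nitroxide) with a Gaussian angular wobble of width
    ``hbond_wobble_deg`` and a uniform spin about the bond.  Fully random
    rigid-body orientations (``hbond_wobble_deg=None``) are available but
    average the solvent's electrostatic field at the radical to zero,
    which real, orientationally correlated solvent does not do.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be non-negative")
    solute = solute if solute is not None else h2no_solute()
    if oop_quad is None and solute.n_atoms == 4:
        oop_quad = H2NO_OOP_QUAD
    rng = np.random.default_rng(seed)
    wat = water_template()
    frames = []
    for _ in range(n_frames):
        sol = solute
        if oop_quad is not None and oop_sigma_deg > 0:
            sol = _distort_oop(
                solute, oop_quad, float(rng.normal(0.0, oop_sigma_deg))
            )
        sol_coords = sol.coords_angstrom
        heavy = sol_coords[sol.charges > 1.5]
        # permanent N-O dipole of the radical (~3 D), negative end at O;
        # drives the Langevin orientation of the solvent
        n_at = np.nonzero(sol.charges == 7)[0]
        o_at = np.nonzero(sol.charges == 8)[0]
        dip_vec = None
        dip_center = sol_coords.mean(axis=0)
        if len(n_at) and len(o_at):
            r_n, r_o = sol_coords[n_at[0]], sol_coords[o_at[0]]
            dip_center = 0.5 * (r_n + r_o)
            dvec = r_n - r_o
            dip_vec = (3.0 / 4.80321) * dvec / np.linalg.norm(dvec)
        placed_o = []
        atoms = list(sol.atoms)
        mol_id = [0] * sol.n_atoms
        for iw in range(n_waters):
            ok = False
            for _try in range(max_attempts_per_water):
                # uniform point in the sphere
                u = rng.random()
                r = box_radius * u ** (1.0 / 3.0)
                v = rng.normal(size=3)
                o_pos = r * v / np.linalg.norm(v)
                if placed_o and np.min(
                    np.linalg.norm(np.array(placed_o) - o_pos, axis=1)
                ) < min_dist:
                    continue
                if len(heavy) and np.min(
                    np.linalg.norm(heavy - o_pos, axis=1)
                ) < solute_min_dist:
                    continue
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not pack water {iw + 1}/{n_waters} after "
                    f"{max_attempts_per_water} attempts; increase box_radius"
                )
            placed_o.append(o_pos)
            if hbond_wobble_deg is None or dip_vec is None:
                R = _random_rotation(rng)
            else:
                # align the water dipole with the local field of the
                # solute's N-O dipole (Langevin orientational response)
                e_loc = _dipole_field(dip_vec, dip_center, o_pos)
                bisector = np.array(
                    [1.0 + math.cos(_WATER_ANGLE), math.sin(_WATER_ANGLE),
                     0.0]
                )
                R = _oriented_rotation(rng, bisector, e_loc,
                                       hbond_wobble_deg)
            geom = wat @ R.T + o_pos
            for sym, z, pos in zip(("O", "H", "H"), (8, 1, 1), geom):
                atoms.append(Atom(sym, z, tuple(pos)))
            mol_id.extend([iw + 1] * 3)
        frames.append(AtomicSystem(
            atoms=atoms, net_charge=solute.net_charge,
            multiplicity=solute.multiplicity,
            mol_id=np.array(mol_id),
            solute_mask=np.array(
                [True] * sol.n_atoms + [False] * (3 * n_waters)
            ),
        ))
    return frames


# ---------------------------------------------------------------------------
# per-snapshot evaluation
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Settings of the per-snapshot multilevel hcc evaluation."""

    functional_name: str = "pbe0"
    grid_level: int = 2
    solute_basis: str = "sto-3g"
    water_basis: str = "sto-3g"
    droplet_radius: float = 13.0     # Å
    qm_radius: float = 3.5           # Å, from the solute center of mass
    n_qm: int | None = None          # override: fixed QM-shell water count
    water_point: str = "O"
    scheme: str = "NO"
    n_active: int = 0
    embedding: str = "fq"            # none | fixed | fq
    parameter_set: str | None = None
    tau: float = DEFAULT_TAU
    lindep_tol: float = DEFAULT_LINDEP
    conv_grad: float = 1e-6
    conv_energy: float = 1e-9
    max_iter: int = 100
    polarize_before_partition: bool = True
    include_nuclear_potential: bool = True
    hcc_elements: tuple = ("N",)
    oop_quad: tuple | None = None
    no_pair: tuple | None = None

    def functional_spec(self):
        return functional(self.functional_name, grid_level=self.grid_level)


def _basis_labels(qm: AtomicSystem, cfg: PipelineConfig):
    return [
        cfg.solute_basis if qm.solute_mask[i] else cfg.water_basis
        for i in range(qm.n_atoms)
    ]


def prepare_frame(frame: AtomicSystem, cfg: PipelineConfig):
    """Carve the droplet and split layers for one frame."""
    droplet = carve_droplet(frame, cfg.droplet_radius, cfg.water_point)
    qm, part, layer, info = select_layers(
        droplet, cfg.qm_radius, cfg.n_active, scheme=cfg.scheme,
        embedding=cfg.embedding, parameter_set=cfg.parameter_set,
        water_point=cfg.water_point, no_pair=cfg.no_pair, n_qm=cfg.n_qm,
    )
    qm = qm.with_basis(_basis_labels(qm, cfg))
    return droplet, qm, part, layer, info


def run_variant(
    engine: SCFEngine,
    qm: AtomicSystem,
    part,
    layer: EmbeddingLayer | None,
    cfg: PipelineConfig,
) -> dict:
    """Multilevel SCF + hcc for one prepared QM system/partition/layer."""
    coupler = None
    if layer is not None and layer.n_sites:
        coupler = EmbeddingCoupler(
            engine, layer, include_nuclear=cfg.include_nuclear_potential
        )
    hook = coupler.hook if coupler else None
    guess = sad_guess(qm, engine)
    pur = purify_guess(
        qm, guess, engine=engine,
        fock_hook=hook if cfg.polarize_before_partition else None,
    )
    pd_, space = partition_densities(
        pur, part, engine.basis, tau=cfg.tau, lindep_tol=cfg.lindep_tol
    )
    frozen = frozen_inactive_terms(engine, pd_)
    res = run_uml_scf(
        engine, pd_, space, frozen, max_iter=cfg.max_iter,
        conv_energy=cfg.conv_energy, conv_grad=cfg.conv_grad,
        fock_hook=hook,
    )
    dens = SpinResolvedDensity(
        D_alpha=res.partitioned.D_A_alpha + res.partitioned.D_B_alpha,
        D_beta=res.partitioned.D_A_beta + res.partitioned.D_B_beta,
        S=engine.S, n_alpha=qm.n_alpha, n_beta=qm.n_beta,
    )
    nuclei = [
        i for i, a in enumerate(qm.atoms)
        if a.symbol in cfg.hcc_elements and qm.solute_mask[i]
    ]
    hf = hyperfine(qm, engine.basis, dens, nuclei=nuclei,
                   active_atoms=sorted(part.active_atoms))
    out = {
        "energy": res.energy,
        "n_iter": res.n_iter,
        "hcc": {f"{el}{idx}": float(a)
                for (idx, el, _), a in zip(hf.nuclei, hf.A_iso)},
        "hcc_first": float(hf.A_iso[0]) if len(hf.A_iso) else np.nan,
        "breakdown": res.energy_breakdown,
        "result": res,
        "hyperfine": hf,
    }
    return out


def run_snapshot(frame: AtomicSystem, cfg: PipelineConfig) -> dict:
    """Full pipeline on one frame; returns a flat result row."""
    droplet, qm, part, layer, info = prepare_frame(frame, cfg)
    engine = SCFEngine(qm, cfg.functional_spec())
    var = run_variant(engine, qm, part, layer, cfg)
    row = {
        "scheme": cfg.scheme, "n_active": cfg.n_active,
        "embedding": cfg.embedding, "hcc_gauss": var["hcc_first"],
        "energy_hartree": var["energy"], **info,
    }
    if cfg.oop_quad is not None:
        row["oop_deg"] = out_of_plane_angle(frame, cfg.oop_quad)
    return row


def run_ensemble(frames, cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Per-snapshot hcc table and Eq-17-style ensemble summary."""
    rows = []
    for i, frame in enumerate(frames):
        row = run_snapshot(frame, cfg)
        row["frame"] = i
        rows.append(row)
        log.info("frame %d: hcc = %.3f G", i, row["hcc_gauss"])
    df = pd.DataFrame(rows)
    stats = ensemble_stats(df["hcc_gauss"].to_numpy())
    stats.metadata.update(
        scheme=cfg.scheme, n_active=cfg.n_active, embedding=cfg.embedding
    )
    return df, stats.summary()
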