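"""HDF5 checkpoints for densities, partitions and orbital spaces.

One container schema serves both the initial purified densities (for reuse
across active-space scans) and converged partitioned states: matrices live
under named groups, scalars and strings under attributes.
"""
from __future__ import annotations

import json

import h5py
import numpy as np

from .initial_density import SpinResolvedDensity
from .partition import ActiveOrbitalSpace, PartitionedDensity


def save_checkpoint(
    path,
    density: SpinResolvedDensity | None = None,
    partitioned: PartitionedDensity | None = None,
    orbital_space: ActiveOrbitalSpace | None = None,
    metadata: dict | None = None,
):
    with h5py.File(path, "w") as fh:
        if metadata:
            fh.attrs["metadata"] = json.dumps(metadata, default=str)
        if density is not None:
            g = fh.create_group("density")
            g.create_dataset("D_alpha", data=density.D_alpha)
            g.create_dataset("D_beta", data=density.D_beta)
            g.create_dataset("S", data=density.S)
            g.attrs["n_alpha"] = density.n_alpha
            g.attrs["n_beta"] = density.n_beta
        if partitioned is not None:
            g = fh.create_group("partitioned")
            for name in ("D_A_alpha", "D_A_beta", "D_B_alpha", "D_B_beta",
                         "S"):
                g.create_dataset(name, data=getattr(partitioned, name))
        if orbital_space is not None:
            g = fh.create_group("orbital_space")
            for name in ("C_occ_alpha", "C_occ_beta", "C_virt_alpha",
                         "C_virt_beta"):
                g.create_dataset(name, data=getattr(orbital_space, name))


def load_checkpoint(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as fh:
        if "metadata" in fh.attrs:
            out["metadata"] = json.loads(fh.attrs["metadata"])
        if "density" in fh:
            g = fh["density"]
            out["density"] = SpinResolvedDensity(
                D_alpha=np.array(g["D_alpha"]),
                D_beta=np.array(g["D_beta"]),
                S=np.array(g["S"]),
                n_alpha=int(g.attrs["n_alpha"]),
                n_beta=int(g.attrs["n_beta"]),
            )
        if "partitioned" in fh:
            g = fh["partitioned"]
            out["partitioned"] = PartitionedDensity(
                **{k: np.array(g[k]) for k in
                   ("D_A_alpha", "D_A_beta", "D_B_alpha", "D_B_beta", "S")}
            )
        if "orbital_space" in fh:
            g = fh["orbital_space"]
            out["orbital_space"] = ActiveOrbitalSpace(
                **{k: np.array(g[k]) for k in
                   ("C_occ_alpha", "C_occ_beta", "C_virt_alpha",
                    "C_virt_beta")}
            )
    return out
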