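"""Coordinate and topology I/O.

Coordinates are accepted as GRO (nm) or PDB (Å, converted to nm) files —
single- or multi-model, read through MDAnalysis — with a sidecar topology
CSV whose header is exactly::

    particle_index,lipid_id,species,chain_role,bead_name,mass,is_head

A native multi-frame container (HDF5) stores the topology once plus one
coordinate block and box per frame; it carries a version string and the
optional per-frame tags (temperature or time).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Frame, Topology, Trajectory

NATIVE_VERSION = "lipidstack-container-1"

_RESNAMES = {"CER_NS": "CER", "CHOL": "CHL", "FFA": "FFA", "WATER": "W"}


def read_topology_csv(path) -> Topology:
    df = pd.read_csv(path)
    return Topology(df)


def write_topology_csv(path, topology: Topology) -> None:
    topology.df.to_csv(path, index=False)


def _read_coordinates(path) -> tuple:
    """Return (frames_nm, boxes_nm) from a GRO or PDB file via MDAnalysis."""
    import MDAnalysis as mda

    suffix = Path(path).suffix.lower()
    if suffix not in (".gro", ".pdb"):
        raise ValueError(f"unsupported coordinate format {suffix!r} (use .gro or .pdb)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords, boxes = [], []
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float) / 10.0)  # A -> nm
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
    return coords, boxes


def load_system(coords_path, topology_path) -> tuple:
    """Load and join coordinates + topology into (Topology, Trajectory)."""
    topology = read_topology_csv(topology_path)
    coords, boxes = _read_coordinates(coords_path)
    n = len(coords[0])
    if n != topology.n_particles:
        raise ValueError(
            f"coordinate/topology count mismatch: {topology.n_particles} vs {n}"
        )
    frames = [Frame(c, b) for c, b in zip(coords, boxes)]
    return topology, Trajectory(topology, frames)


def write_gro(path, topology: Topology, frame: Frame, title: str = "lipidstack") -> None:
    """Write one frame as GRO (nm, 0.001 nm precision) via MDAnalysis."""
    import MDAnalysis as mda

    df = topology.df
    lids, resindex = np.unique(df["lipid_id"].to_numpy(), return_inverse=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=len(df),
            n_residues=len(lids),
            atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", df["bead_name"].astype(str).to_numpy())
        resnames = (
            df.groupby("lipid_id", sort=True)["species"].first().map(_RESNAMES)
        )
        u.add_TopologyAttr("resnames", resnames.to_numpy())
        u.add_TopologyAttr("resids", (np.arange(len(lids)) % 99999) + 1)
        u.atoms.positions = frame.coordinates * 10.0  # nm -> A
        u.dimensions = np.r_[frame.box * 10.0, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# native multi-frame container (HDF5)
# ---------------------------------------------------------------------------

def write_native(path, topology: Topology, frames) -> None:
    import h5py

    frames = list(frames)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = NATIVE_VERSION
        g = f.create_group("topology")
        df = topology.df
        for col in ("particle_index", "lipid_id"):
            g.create_dataset(col, data=df[col].to_numpy(np.int64))
        for col in ("species", "chain_role", "bead_name"):
            g.create_dataset(col, data=df[col].astype(str).to_numpy(dtype="S"))
        g.create_dataset("mass", data=df["mass"].to_numpy(float))
        g.create_dataset("is_head", data=df["is_head"].to_numpy(bool))
        f.create_dataset(
            "coordinates", data=np.stack([fr.coordinates for fr in frames])
        )
        f.create_dataset("box", data=np.stack([fr.box for fr in frames]))
        tags = np.array(
            [np.nan if fr.tag is None else float(fr.tag) for fr in frames]
        )
        f.create_dataset("tags", data=tags)


def read_native(path) -> tuple:
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != NATIVE_VERSION:
            raise ValueError(f"unsupported container version {version!r}")
        g = f["topology"]
        df = pd.DataFrame(
            {
                "particle_index": g["particle_index"][:],
                "lipid_id": g["lipid_id"][:],
                "species": g["species"][:].astype(str),
                "chain_role": g["chain_role"][:].astype(str),
                "bead_name": g["bead_name"][:].astype(str),
                "mass": g["mass"][:],
                "is_head": g["is_head"][:],
            }
        )
        topology = Topology(df)
        coords = f["coordinates"][:]
        boxes = f["box"][:]
        tags = f["tags"][:]
    frames = [
        Frame(c, b, None if np.isnan(t) else float(t))
        for c, b, t in zip(coords, boxes, tags)
    ]
    return topology, Trajectory(topology, frames)
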