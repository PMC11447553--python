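"""Core data model for multilayer stratum-corneum lipid membranes.

A system is a :class:`Topology` (one metadata row per particle) joined to one
or more :class:`Frame` objects holding coordinates in nm and an orthorhombic
box.  The bilayer normal is always the z axis; coordinates are wrapped in
x-y but must remain unwrapped (monotone) in z, since every thickness
measurement relies on a monotone z coordinate.

Lipid species follow the CER NS / CHOL / FFA ternary system: each CER NS
carries an acyl (C24) and a sphingosine (C18) chain, CHOL and FFA carry one
chain each.  Headgroup beads for the coarse-grained representation are, by
convention, MHEAD2/AMIDE/OH1/OH2 (CER NS), HEAD (FFA) and CHEAD (CHOL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SPECIES = ("CER_NS", "CHOL", "FFA", "WATER")
CHAIN_ROLES = ("acyl", "sphingosine", "sterol", "fatty", "none")

#: Tail types used by composition / neighbor / area analyses
TAIL_TYPES = ("CER_acyl", "CER_sph", "CHOL", "FFA")

#: Headgroup bead names per species in the CG representation
CG_HEAD_BEADS = {
    "CER_NS": ("MHEAD2", "AMIDE", "OH1", "OH2"),
    "FFA": ("HEAD",),
    "CHOL": ("CHEAD",),
}

TOPOLOGY_COLUMNS = (
    "particle_index",
    "lipid_id",
    "species",
    "chain_role",
    "bead_name",
    "mass",
    "is_head",
)

#: chain_role of the single tail of each one-chain species
_SINGLE_CHAIN_ROLE = {"CHOL": "sterol", "FFA": "fatty"}


class TopologyError(ValueError):
    """Raised when a topology table violates the data-model contract."""


class Topology:
    """Validated per-particle metadata table.

    Wraps a :class:`pandas.DataFrame` with columns
    ``particle_index, lipid_id, species, chain_role, bead_name, mass,
    is_head`` sorted by ``particle_index``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
        if missing:
            raise TopologyError(f"topology missing columns: {missing}")
        df = df.loc[:, list(TOPOLOGY_COLUMNS)].copy()
        df["particle_index"] = df["particle_index"].astype(int)
        df["lipid_id"] = df["lipid_id"].astype(int)
        df["mass"] = df["mass"].astype(float)
        df["is_head"] = df["is_head"].astype(bool)
        unknown = set(df["species"]) - set(SPECIES)
        if unknown:
            raise TopologyError(f"unknown species: {sorted(unknown)}")
        unknown = set(df["chain_role"]) - set(CHAIN_ROLES)
        if unknown:
            raise TopologyError(f"unknown chain_role: {sorted(unknown)}")
        if (df["mass"] <= 0).any():
            raise TopologyError("particle masses must be > 0")
        if (df["particle_index"] < 0).any():
            raise TopologyError("particle_index must be >= 0")
        df = df.sort_values("particle_index", kind="stable").reset_index(drop=True)
        if df["particle_index"].duplicated().any():
            raise TopologyError("duplicate particle_index")
        # every non-water lipid must expose at least one head bead
        nonwater = df[df["species"] != "WATER"]
        heads_per_lipid = nonwater.groupby("lipid_id")["is_head"].sum()
        if (heads_per_lipid == 0).any():
            bad = heads_per_lipid.index[heads_per_lipid == 0].tolist()[:5]
            raise TopologyError(f"lipids without head beads: {bad}")
        # CER NS lipids must have both chains
        cer = nonwater[nonwater["species"] == "CER_NS"]
        if len(cer):
            roles = cer[~cer["is_head"]].groupby("lipid_id")["chain_role"].agg(set)
            bad = roles.index[~roles.apply({"acyl", "sphingosine"}.issubset)]
            if len(bad):
                raise TopologyError(
                    f"CER_NS lipids missing a chain role: {bad.tolist()[:5]}"
                )
        self.df = df
        self._chain_cache = None

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_particles(self) -> int:
        return len(self.df)

    @property
    def masses(self) -> np.ndarray:
        return self.df["mass"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        return self.df["species"].to_numpy()

    @property
    def is_head(self) -> np.ndarray:
        return self.df["is_head"].to_numpy()

    def lipids(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group non-water particles by lipid id."""
        non_water = self.df[self.df["species"] != "WATER"]
        return non_water.groupby("lipid_id", sort=True)

    def chain_indices(self, lipid_id: int, chain_role: str) -> np.ndarray:
        """Row indices (topology order) of the non-head beads of one chain.

        Pseudo-hydrogens (bead names matching ``H<nn>a/b``) are excluded, so
        the returned beads are the chain's ordered backbone.
        """
        if self._chain_cache is None:
            df = self.df
            backbone = (
                ~df["is_head"].to_numpy()
                & (df["species"].to_numpy() != "WATER")
                & ~df["bead_name"].str.match(r"^H\d\d[ab]$").to_numpy()
            )
            sub = df[backbone]
            self._chain_cache = {
                key: idx.to_numpy()
                for key, idx in sub.groupby(
                    ["lipid_id", "chain_role"], sort=False
                ).groups.items()
            }
        return self._chain_cache.get((lipid_id, chain_role), np.empty(0, dtype=int))


@dataclass
class Frame:
    """One configuration: coordinates (nm), orthorhombic box (nm), optional tag.

    ``tag`` carries a temperature in °C (thermotropic sweeps) or a time in ns.
    """

    coordinates: np.ndarray
    box: np.ndarray
    tag: Optional[float] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if self.box.shape != (3,) or (self.box <= 0).any():
            raise ValueError("box must be three positive lengths (Lx, Ly, Lz)")

    @property
    def n_particles(self) -> int:
        return len(self.coordinates)


@dataclass
class Trajectory:
    """Topology shared across an ordered list of frames."""

    topology: Topology
    frames: list

    def __post_init__(self):
        for f in self.frames:
            if f.n_particles != self.topology.n_particles:
                raise ValueError(
                    f"frame has {f.n_particles} particles, topology has "
                    f"{self.topology.n_particles}"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TailInstance:
    """One lipid chain reduced to its analysis attributes.

    ``conformer`` is ``extended``/``hairpin`` for CER chains and
    ``not_applicable`` for CHOL and FFA.  ``com`` is the mass-weighted center
    of the chain's non-head beads.
    """

    lipid_id: int
    tail_type: str  # one of TAIL_TYPES
    conformer: str  # extended | hairpin | not_applicable
    leaflet: int
    com: np.ndarray

    def __post_init__(self):
        if self.tail_type not in TAIL_TYPES:
            raise ValueError(f"bad tail_type {self.tail_type!r}")
        is_cer = self.tail_type in ("CER_acyl", "CER_sph")
        if is_cer != (self.conformer != "not_applicable"):
            raise ValueError(
                "conformer must be extended/hairpin exactly for CER tails"
            )
        self.com = np.asarray(self.com, dtype=float)


def tail_com(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted center of a chain's beads (no periodic unwrapping).

    Chains never span the box in z, and sit within one lattice cell in x-y,
    so the plain weighted mean is the correct center of mass.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if len(coordinates) == 0 or total <= 0:
        raise ValueError("tail needs >= 1 bead with positive total mass")
    return (coordinates * masses[:, None]).sum(axis=0) / total


def pbc_xy_distance(a, b, box) -> float:
    """Minimum-image Euclidean distance in the x-y plane."""
    box = np.asarray(box, dtype=float)[:2]
    if (box <= 0).any():
        raise ValueError("box lengths must be positive")
    d = np.asarray(a, dtype=float)[:2] - np.asarray(b, dtype=float)[:2]
    d -= box * np.round(d / box)
    return float(np.sqrt((d**2).sum()))


def min_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention componentwise (vectorized)."""
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def unwrap_chain_xy(coords: np.ndarray, box) -> np.ndarray:
    """Undo lateral wrapping of a connected chain (z is never wrapped).

    Beads are placed relative to the first bead by minimum image in x and y,
    restoring a contiguous chain for director and center-of-mass math.
    """
    coords = np.asarray(coords, dtype=float)
    box_xy = np.asarray(box, dtype=float)[:2]
    out = coords.copy()
    d = out[:, :2] - out[0, :2]
    out[:, :2] = out[0, :2] + d - box_xy * np.round(d / box_xy)
    return out


def lipid_com_table(frame: Frame, topology: Topology) -> pd.DataFrame:
    """Whole-lipid (all beads, mass-weighted) centers of mass of non-water lipids.

    Returns a DataFrame indexed by lipid_id with columns x, y, z.
    """
    df = topology.df
    mask = (df["species"] != "WATER").to_numpy()
    w = df["mass"].to_numpy()[mask]
    xyz = frame.coordinates[mask] * w[:, None]
    lid = df["lipid_id"].to_numpy()[mask]
    out = pd.DataFrame(xyz, columns=["x", "y", "z"])
    out["m"] = w
    out["lipid_id"] = lid
    g = out.groupby("lipid_id").sum()
    com = g[["x", "y", "z"]].div(g["m"], axis=0)
    return com


def head_centroid_z(frame: Frame, topology: Topology) -> pd.Series:
    """Mass-weighted head-bead centroid z per non-water lipid."""
    df = topology.df
    mask = (df["is_head"] & (df["species"] != "WATER")).to_numpy()
    w = df["mass"].to_numpy()[mask]
    z = frame.coordinates[mask, 2] * w
    lid = df["lipid_id"].to_numpy()[mask]
    t = pd.DataFrame({"wz": z, "w": w, "lipid_id": lid}).groupby("lipid_id").sum()
    return t["wz"] / t["w"]
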