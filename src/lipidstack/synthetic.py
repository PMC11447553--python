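"""Synthetic multilayer configurations with known ground truth.

The generator emulates self-assembled three-bilayer (six-leaflet)
CER NS/CHOL/FFA stacks: ~2000 lipids on a ~10x10 nm in-plane area, flanking
water slabs (40 water molecules per lipid, 4 per CG water bead), ~35 % of
eligible CERs in the extended conformation, and temperature-controlled
orientational disorder.  Chains are straight bead strings placed on a
jittered triangular lattice per leaflet; headgroup beads sit at the leaflet
head planes, so local bilayer thickness is imposed exactly by construction
and every analysis stage can be validated against generator truth.

Lateral domains are imposed, not emergent: regions of the central bilayer
may carry their own head-plane separation (thickness) and a per-tail-type
composition enrichment realized by weighted sampling without replacement,
which preserves the global composition exactly.

Orientational disorder is a von Mises-Fisher distribution about the bilayer
normal with concentration ``orientation_kappa``; the mapping between
concentration and the expected nematic order parameter S2 is the closed
form E[P2] = 1 - 3(coth k - 1/k)/k, inverted numerically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Frame, TailInstance, Topology, Trajectory

# geometry constants (nm)
CG_BEAD_SPACING = 0.47
ATOM_CARBON_RISE = 0.127
CH_BOND_LENGTH = 0.109
INTERBILAYER_GAP = 0.8
HEAD_JITTER_SD = 0.03
XY_JITTER_SD = 0.05
WATER_OFFSET = 0.4
WATER_BEAD_DENSITY = 8.35  # CG beads / nm^3 (~33.4 waters/nm^3, 4 per bead)
WATERS_PER_BEAD = 4

# CG bead templates: (head beads with masses), per-chain tail bead counts
_CG_HEADS = {
    "CER_NS": (("MHEAD2", 72.0), ("AMIDE", 58.0), ("OH1", 17.0), ("OH2", 17.0)),
    "FFA": (("HEAD", 59.0),),
    "CHOL": (("CHEAD", 59.0),),
}
_CG_TAILS = {  # role -> (n_beads, bead mass, name prefix)
    ("CER_NS", "acyl"): (5, 56.0, "ACL"),
    ("CER_NS", "sphingosine"): (4, 56.0, "SPH"),
    ("FFA", "fatty"): (5, 56.0, "FFA"),
    ("CHOL", "sterol"): (4, 81.0, "CHL"),
}
_ATOM_TAILS = {
    ("CER_NS", "acyl"): (24, 14.0, "C"),
    ("CER_NS", "sphingosine"): (18, 14.0, "C"),
    ("FFA", "fatty"): (24, 14.0, "C"),
    ("CHOL", "sterol"): (9, 14.0, "C"),
}
WATER_BEAD_MASS = 72.0


@dataclass
class Region:
    """A lateral domain of the central bilayer.

    ``kind`` is ``half_plane`` (x < x_split*Lx when side='left', the rest
    when side='right') or ``disc`` (min-image distance to ``center`` given as
    box fractions <= radius_nm).  ``enrichment`` multiplies the sampling
    weight of chains by tail type (keys from CER_acyl, CER_sph, CHOL, FFA).
    """

    kind: str = "half_plane"
    thickness_nm: float = 5.4
    enrichment: dict = field(default_factory=dict)
    x_split: float = 0.5
    side: str = "left"
    center: tuple = (0.5, 0.5)
    radius_nm: float = 3.0

    def contains(self, xy: np.ndarray, box: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.kind == "half_plane":
            m = xy[:, 0] < self.x_split * box[0]
            return m if self.side == "left" else ~m
        if self.kind == "disc":
            c = np.asarray(self.center) * box[:2]
            d = xy - c
            d -= box[:2] * np.round(d / box[:2])
            return (d**2).sum(axis=1) <= self.radius_nm**2
        raise ValueError(f"unknown region kind {self.kind!r}")

    def weight(self, tail_type_weights: np.ndarray) -> np.ndarray:
        return tail_type_weights


def table2_like_domains():
    """Two half-plane domains with the thin-CHOL/sphingosine-rich vs
    thick-FFA/acyl-rich structure of phase-separating mixtures.

    Thicknesses 5.16 / 5.78 nm; enrichment weights chosen so that all four
    tail types show their characteristic thickness correlation (CHOL and
    sphingosine enriched in the thin domain, FFA and acyl in the thick one).
    Use with a 1:0.2:1 CER/CHOL/FFA molar ratio.
    """
    return [
        Region(kind="half_plane", side="left", thickness_nm=5.16,
               enrichment={"CHOL": 3.0, "CER_sph": 2.0, "CER_acyl": 0.5}),
        Region(kind="half_plane", side="right", thickness_nm=5.78,
               enrichment={"FFA": 2.0, "CER_acyl": 2.5, "CHOL": 0.4}),
    ]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multilayer."""

    n_lipids: int = 2000
    molar_ratio: tuple = (1.0, 0.5, 1.0)  # CER NS : CHOL : FFA
    n_leaflets: int = 6
    area_per_chain: float = 0.20  # nm^2
    fraction_extended: float = 0.35
    thickness_nm: float = 5.4
    domain_spec: list = field(default_factory=list)
    orientation_kappa: float = 150.0
    water_per_lipid: float = 40.0
    resolution: str = "cg"  # 'cg' | 'atomistic'
    seed: int = 0


@dataclass
class SyntheticSystem:
    topology: Topology
    frame: Frame
    truth: dict


# ---------------------------------------------------------------------------
# orientation statistics
# ---------------------------------------------------------------------------

def s2_from_kappa(kappa: float) -> float:
    """Expected P2(cos tilt) for a von Mises-Fisher tilt distribution."""
    if np.isinf(kappa):
        return 1.0
    if kappa < 1e-8:
        return 0.0
    if kappa < 0.1:
        return kappa**2 / 15.0
    return 1.0 - 3.0 * (1.0 / np.tanh(kappa) - 1.0 / kappa) / kappa


def kappa_from_s2(s2: float) -> float:
    """Invert :func:`s2_from_kappa` (s2 in [0, 1))."""
    if s2 <= 0:
        return 0.0
    if s2 >= 1:
        return np.inf
    hi = max(10.0, 6.0 / (1.0 - s2))
    return float(brentq(lambda k: s2_from_kappa(k) - s2, 1e-6, hi, xtol=1e-10))


def _sample_tilt_directions(kappa: float, n: int, rng) -> np.ndarray:
    """Unit vectors concentrated about +z (z component >= 0)."""
    u1 = rng.random(n)
    u2 = rng.random(n)
    if np.isinf(kappa):
        d = np.zeros((n, 3))
        d[:, 2] = 1.0
        return d
    if kappa < 1e-12:
        w = u1  # uniform hemisphere: cos(theta) ~ U[0, 1]
    else:
        w = 1.0 + np.log(u1 + (1.0 - u1) * np.exp(-2.0 * kappa)) / kappa
        w = np.abs(np.clip(w, -1.0, 1.0))
    phi = 2.0 * np.pi * u2
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = exact - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return base


def species_counts(n_lipids: int, molar_ratio) -> dict:
    counts = _largest_remainder(n_lipids, molar_ratio)
    out = dict(zip(("CER_NS", "CHOL", "FFA"), counts))
    for sp, r, c in zip(out, molar_ratio, counts):
        if r > 0 and c < 1:
            raise ValueError(
                f"composition not representable: {sp} ratio {r} yields 0 lipids"
            )
    return out


def mixed_tail_composition(molar_ratio=(1.0, 0.5, 1.0), fraction_extended=0.35) -> dict:
    """Six-class tail fractions of a perfectly mixed central bilayer."""
    rc, rh, rf = molar_ratio
    total = 2 * rc + rh + rf
    acyl = sph = rc / total
    return {
        "CER_acyl_ext": acyl * fraction_extended,
        "CER_acyl_hp": acyl * (1 - fraction_extended),
        "CER_sph_ext": sph * fraction_extended,
        "CER_sph_hp": sph * (1 - fraction_extended),
        "CHOL": rh / total,
        "FFA": rf / total,
    }


def waters_per_outer_lipid(n_waters: float, n_lipids: int, n_leaflets: int) -> float:
    """Water molecules per lipid of the two outer leaflets of a stack."""
    return n_waters / (2.0 * n_lipids / n_leaflets)


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------

def _triangular_lattice(n_sites: int, area_per_site: float):
    a = np.sqrt(2.0 * area_per_site / np.sqrt(3.0))
    h = a * np.sqrt(3.0) / 2.0
    ncol = int(np.ceil(np.sqrt(n_sites * h / a)))
    nrow = int(np.ceil(n_sites / ncol))
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    x = (cols + 0.25 + 0.5 * (rows % 2)) * a
    y = (rows + 0.5) * h
    sites = np.column_stack([x.ravel(), y.ravel()])
    box_xy = np.array([ncol * a, nrow * h])
    return sites % box_xy, box_xy


def _nearest_free(site_xy, sites, free, box_xy):
    idx = np.flatnonzero(free)
    d = sites[idx] - site_xy
    d -= box_xy * np.round(d / box_xy)
    return idx[np.argmin((d**2).sum(axis=1))]


# ---------------------------------------------------------------------------
# the multilayer generator
# ---------------------------------------------------------------------------

def _leaflet_is_lower(leaflet: int) -> bool:
    return leaflet % 2 == 1


def _adjacent_leaflet(leaflet: int, n_leaflets: int):
    """Leaflet across the head plane (for extended CER sphingosine chains)."""
    if _leaflet_is_lower(leaflet):
        return leaflet - 1 if leaflet > 1 else None
    return leaflet + 1 if leaflet < n_leaflets else None


def make_multilayer(spec: SyntheticSpec, orientation_key: int = 0) -> SyntheticSystem:
    """Build one multilayer configuration with ground truth.

    ``orientation_key`` selects an independent substream for the tilt
    directions only, so temperature sweeps can vary disorder while keeping
    the lateral structure (and hence the topology) identical.
    """
    if spec.n_leaflets < 2 or spec.n_leaflets % 2:
        raise ValueError("n_leaflets must be even and >= 2")
    K = spec.n_leaflets
    rng = np.random.default_rng([spec.seed, 1])
    rng_orient = np.random.default_rng([spec.seed, 2, orientation_key])
    rng_water = np.random.default_rng([spec.seed, 3])

    counts = species_counts(spec.n_lipids, spec.molar_ratio)
    tails_tpl = _CG_TAILS if spec.resolution == "cg" else _ATOM_TAILS
    spacing = CG_BEAD_SPACING if spec.resolution == "cg" else ATOM_CARBON_RISE

    # --- allocate lipids to home leaflets, sample conformers ---------------
    lipid_rows = []  # (lipid_id, species, home_leaflet, conformer)
    lipid_id = 0
    for sp, n in counts.items():
        per_leaf = _largest_remainder(n, np.ones(K))
        per_leaf = per_leaf[rng.permutation(K)]
        for L0, nl in enumerate(per_leaf):
            L = L0 + 1
            for _ in range(int(nl)):
                lipid_rows.append([lipid_id, sp, L, "not_applicable"])
                lipid_id += 1
    lipids = pd.DataFrame(
        lipid_rows, columns=["lipid_id", "species", "home_leaflet", "conformer"]
    )
    # conformers for CERs: fraction_extended applies to eligible homes
    for L in range(1, K + 1):
        cer_idx = lipids.index[
            (lipids["species"] == "CER_NS") & (lipids["home_leaflet"] == L)
        ]
        if _adjacent_leaflet(L, K) is None:
            lipids.loc[cer_idx, "conformer"] = "hairpin"
            continue
        n_ext = int(round(spec.fraction_extended * len(cer_idx)))
        ext = rng.choice(cer_idx, size=n_ext, replace=False) if n_ext else []
        lipids.loc[cer_idx, "conformer"] = "hairpin"
        lipids.loc[ext, "conformer"] = "extended"

    # --- chains per leaflet -------------------------------------------------
    # chain entity: dict(lipid_id, species, role, leaflet, anchor_leaflet,
    #                    outward, partner_of)
    entities = {L: [] for L in range(1, K + 1)}  # placement units per leaflet
    for row in lipids.itertuples(index=False):
        if row.species == "CER_NS":
            if row.conformer == "hairpin":
                entities[row.home_leaflet].append(
                    ("CER_hp", row.lipid_id, row.home_leaflet)
                )
            else:
                adj = _adjacent_leaflet(row.home_leaflet, K)
                entities[row.home_leaflet].append(
                    ("CER_ext_acyl", row.lipid_id, row.home_leaflet)
                )
                entities[adj].append(("CER_ext_sph", row.lipid_id, row.home_leaflet))
        else:
            entities[row.home_leaflet].append((row.species, row.lipid_id, row.home_leaflet))

    chains_per_leaflet = {
        L: sum(2 if e[0] == "CER_hp" else 1 for e in ents)
        for L, ents in entities.items()
    }
    sites, box_xy = _triangular_lattice(
        max(chains_per_leaflet.values()), spec.area_per_chain
    )

    # --- head-plane geometry ------------------------------------------------
    t0, gap = spec.thickness_nm, INTERBILAYER_GAP
    n_bilayers = K // 2
    n_water_beads = int(round(spec.n_lipids * spec.water_per_lipid / WATERS_PER_BEAD))
    slab_h = (n_water_beads / 2.0) / (WATER_BEAD_DENSITY * box_xy[0] * box_xy[1])
    z0 = slab_h + WATER_OFFSET + 0.2
    planes = np.empty(K)
    z = z0
    for b in range(n_bilayers):
        planes[2 * b] = z
        planes[2 * b + 1] = z + t0
        z += t0 + gap
    central_pair = (K // 2, K // 2 + 1)  # 1-based leaflet indices
    mid = 0.5 * (planes[central_pair[0] - 1] + planes[central_pair[1] - 1])
    box = np.array([box_xy[0], box_xy[1], planes[-1] + WATER_OFFSET + slab_h + 0.2])

    def region_of(xy: np.ndarray) -> int:
        for i, reg in enumerate(spec.domain_spec):
            if reg.contains(xy, box)[0]:
                return i
        return -1

    def plane_z(leaflet: int, xy: np.ndarray) -> float:
        base = planes[leaflet - 1]
        if spec.domain_spec and leaflet in central_pair:
            i = region_of(xy)
            if i >= 0:
                t = spec.domain_spec[i].thickness_nm
                return mid - t / 2 if leaflet == central_pair[0] else mid + t / 2
        return base

    # --- site assignment ----------------------------------------------------
    _ENTITY_TAILTYPE = {
        "FFA": "FFA",
        "CHOL": "CHOL",
        "CER_ext_acyl": "CER_acyl",
        "CER_ext_sph": "CER_sph",
    }

    def entity_weight(ent, xy) -> float:
        i = region_of(xy)
        if i < 0:
            return 1.0
        enr = spec.domain_spec[i].enrichment
        if ent[0] == "CER_hp":
            return 0.5 * (enr.get("CER_acyl", 1.0) + enr.get("CER_sph", 1.0))
        return enr.get(_ENTITY_TAILTYPE[ent[0]], 1.0)

    # chain placements: (lipid_id, species, role, leaflet, site_xy, anchor_leaflet, outward)
    placements = []
    for L in range(1, K + 1):
        ents = entities[L]
        free = np.ones(len(sites), dtype=bool)
        order = rng.permutation(len(sites))
        use_weights = bool(spec.domain_spec) and L in central_pair
        remaining = list(rng.permutation(len(ents)))

        def place(ent, site_idx):
            free[site_idx] = False
            xy = sites[site_idx]
            kind, lid, home = ent
            if kind == "CER_hp":
                partner = _nearest_free(xy, sites, free, box_xy)
                free[partner] = False
                placements.append((lid, "CER_NS", "acyl", L, xy, home, False))
                placements.append(
                    (lid, "CER_NS", "sphingosine", L, sites[partner], home, False)
                )
            elif kind == "CER_ext_acyl":
                placements.append((lid, "CER_NS", "acyl", L, xy, home, False))
            elif kind == "CER_ext_sph":
                # enters leaflet L from the adjacent home plane, pointing outward
                placements.append((lid, "CER_NS", "sphingosine", L, xy, home, True))
            elif kind == "CHOL":
                placements.append((lid, "CHOL", "sterol", L, xy, home, False))
            else:
                placements.append((lid, "FFA", "fatty", L, xy, home, False))

        if not use_weights:
            it = iter(order)
            for ei in remaining:
                site_idx = next(i for i in it if free[i])
                place(ents[ei], site_idx)
        else:
            for site_idx in order:
                if not remaining or not free[site_idx]:
                    continue
                w = np.array(
                    [entity_weight(ents[ei], sites[site_idx]) for ei in remaining]
                )
                if w.sum() <= 0:
                    w = np.ones_like(w)
                ei_pos = rng.choice(len(remaining), p=w / w.sum())
                place(ents[remaining.pop(ei_pos)], site_idx)

    # --- build beads --------------------------------------------------------
    heads_tpl = _CG_HEADS
    head_xy = {}  # lipid_id -> xy of its acyl/primary site (for head beads)
    names, massv, lidv, spv, rolev, headv = [], [], [], [], [], []
    coords = []

    # tilt directions, one per chain, drawn in placement order
    dirs = _sample_tilt_directions(
        spec.orientation_kappa, len(placements), rng_orient
    )
    jit_xy = rng.normal(0.0, XY_JITTER_SD, size=(len(placements), 2))
    jit_z = rng.normal(0.0, HEAD_JITTER_SD, size=len(placements))

    chain_records = []  # for ground truth: (lipid_id, role, leaflet, site_xy)
    for ci, (lid, sp, role, L, xy, home, outward) in enumerate(placements):
        n_beads, bead_mass, prefix = tails_tpl[(sp, role)]
        anchor = plane_z(home, xy) + jit_z[ci]
        inward = 1.0 if _leaflet_is_lower(home) else -1.0
        sign = -inward if outward else inward
        d = dirs[ci] * np.array([1.0, 1.0, sign])
        # an extended-CER sphingosine chain crosses the head region into the
        # adjacent leaflet; offsetting by the inter-bilayer gap places it at
        # the same depth as that leaflet's native chains
        z_start = anchor + (sign * INTERBILAYER_GAP if outward else 0.0)
        start = np.array([xy[0] + jit_xy[ci, 0], xy[1] + jit_xy[ci, 1], z_start])
        for j in range(1, n_beads + 1):
            coords.append(start + d * (spacing * j))
            names.append(f"{prefix}{j}")
            massv.append(bead_mass)
            lidv.append(lid)
            spv.append(sp)
            rolev.append(role)
            headv.append(False)
        chain_records.append((lid, sp, role, L, xy[0], xy[1]))
        is_primary = role in ("acyl", "sterol", "fatty")
        if is_primary:
            head_xy[lid] = (xy + jit_xy[ci], home)

    # head beads at the home head plane, clustered at the primary chain's site
    head_jit = rng.normal(0.0, HEAD_JITTER_SD, size=(len(head_xy), 4))
    for hi, (lid, (xy, home)) in enumerate(sorted(head_xy.items())):
        sp = lipids.loc[lipids["lipid_id"] == lid, "species"].iloc[0]
        zp = plane_z(home, np.asarray(xy))
        for bi, (bname, bmass) in enumerate(heads_tpl[sp]):
            coords.append(np.array([xy[0], xy[1], zp + head_jit[hi, bi]]))
            names.append(bname)
            massv.append(bmass)
            lidv.append(lid)
            spv.append(sp)
            rolev.append("none")
            headv.append(True)

    # water slabs
    lo_slab = (z0 - WATER_OFFSET - slab_h, z0 - WATER_OFFSET)
    hi_slab = (planes[-1] + WATER_OFFSET, planes[-1] + WATER_OFFSET + slab_h)
    n_lo = n_water_beads // 2
    for (za, zb), nw in ((lo_slab, n_lo), (hi_slab, n_water_beads - n_lo)):
        w_xyz = rng_water.random((nw, 3))
        w_xyz[:, 0] *= box[0]
        w_xyz[:, 1] *= box[1]
        w_xyz[:, 2] = za + w_xyz[:, 2] * (zb - za)
        for wi in range(nw):
            coords.append(w_xyz[wi])
            names.append("W")
            massv.append(WATER_BEAD_MASS)
            lidv.append(lipid_id + wi)
            spv.append("WATER")
            rolev.append("none")
            headv.append(False)

    df = pd.DataFrame(
        {
            "particle_index": np.arange(len(coords)),
            "lipid_id": lidv,
            "species": spv,
            "chain_role": rolev,
            "bead_name": names,
            "mass": massv,
            "is_head": headv,
        }
    )
    # order beads within each lipid: heads first, then chains head->tail
    order = df.sort_values(
        ["lipid_id", "is_head", "chain_role", "particle_index"],
        ascending=[True, False, True, True],
        kind="stable",
    ).index
    df = df.loc[order].reset_index(drop=True)
    xyz = np.asarray(coords)[order]
    df["particle_index"] = np.arange(len(df))
    xyz[:, :2] %= box[:2]  # wrap laterally; z stays monotone

    topology = Topology(df)
    frame = Frame(xyz, box)

    # --- ground truth -------------------------------------------------------
    chain_df = pd.DataFrame(
        chain_records, columns=["lipid_id", "species", "role", "leaflet", "x", "y"]
    )
    chain_df["tail_type"] = np.where(
        chain_df["species"] == "CER_NS",
        np.where(chain_df["role"] == "acyl", "CER_acyl", "CER_sph"),
        np.where(chain_df["species"] == "CHOL", "CHOL", "FFA"),
    )
    central = chain_df[chain_df["leaflet"].isin(central_pair)].copy()
    central["region"] = [
        region_of(np.array([x, y])) for x, y in zip(central["x"], central["y"])
    ]
    region_comp = {}
    for ridx, sub in central.groupby("region"):
        frac = sub["tail_type"].value_counts(normalize=True)
        region_comp[int(ridx)] = {
            t: float(frac.get(t, 0.0)) for t in ("CER_acyl", "CER_sph", "CHOL", "FFA")
        }
    eligible = lipids[
        (lipids["species"] == "CER_NS")
        & lipids["home_leaflet"].apply(lambda L: _adjacent_leaflet(L, K) is not None)
    ]
    truth = {
        "seed": spec.seed,
        "box": box.tolist(),
        "head_planes": planes.tolist(),
        "central_bilayer": central_pair,
        "central_midplane": float(mid),
        "thickness_base": t0,
        "regions": [
            {
                "kind": r.kind,
                "thickness_nm": r.thickness_nm,
                "enrichment": dict(r.enrichment),
                "realized_central_composition": region_comp.get(i, {}),
            }
            for i, r in enumerate(spec.domain_spec)
        ],
        "base_region_central_composition": region_comp.get(-1, {}),
        "fraction_extended_realized": float(
            (eligible["conformer"] == "extended").mean() if len(eligible) else 0.0
        ),
        "lipids": lipids,
        "chains": chain_df,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(spec).items()
            if k != "domain_spec"
        },
    }
    return SyntheticSystem(topology=topology, frame=frame, truth=truth)


# ---------------------------------------------------------------------------
# perfectly mixed central bilayer (null-model calibration)
# ---------------------------------------------------------------------------

def make_mixed_central_bilayer(n_tails: int, composition: dict, seed: int,
                               area_per_chain: float = 0.20):
    """Tails on a jittered lattice with i.i.d. types: the mixing-null system.

    ``composition`` maps the six tail classes (CER_acyl_ext, CER_acyl_hp,
    CER_sph_ext, CER_sph_hp, CHOL, FFA) to fractions summing to 1.
    Returns (list of TailInstance, box).
    """
    if n_tails < 50:
        warnings.warn("fewer than 50 tails: pair statistics will be unreliable")
    classes = list(composition)
    p = np.array([composition[c] for c in classes], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    sites, box_xy = _triangular_lattice(n_tails, area_per_chain)
    sites = sites[rng.permutation(len(sites))[:n_tails]]
    xy = sites + rng.normal(0, XY_JITTER_SD, size=sites.shape)
    z = 2.5 + rng.normal(0, XY_JITTER_SD, size=n_tails)
    labels = rng.choice(len(classes), size=n_tails, p=p)
    box = np.array([box_xy[0], box_xy[1], 5.0])
    tails = []
    for i in range(n_tails):
        cls = classes[labels[i]]
        if cls.startswith("CER"):
            ttype = "CER_acyl" if "acyl" in cls else "CER_sph"
            conf = "extended" if cls.endswith("ext") else "hairpin"
        else:
            ttype, conf = cls, "not_applicable"
        tails.append(
            TailInstance(i, ttype, conf, 1, np.array([xy[i, 0] % box[0],
                                                      xy[i, 1] % box[1], z[i]]))
        )
    return tails, box


# ---------------------------------------------------------------------------
# temperature sweeps
# ---------------------------------------------------------------------------

@dataclass
class HingeDisorderModel:
    """Piecewise-linear order/area model with a known breakpoint.

    Defaults describe a well-ordered phase (S2 ~ 0.91) that melts past the
    breakpoint, crossing the ordered/fluid boundary (0.8) near 80 °C.
    """

    breakpoint: float = 65.0
    s2_at_break: float = 0.90
    s2_slope_below: float = -3e-4
    s2_slope_above: float = -6e-3
    area_slope_below: float = 1e-4
    area_slope_above: float = 1.5e-3

    def s2(self, T: float) -> float:
        slope = self.s2_slope_below if T <= self.breakpoint else self.s2_slope_above
        return float(np.clip(self.s2_at_break + slope * (T - self.breakpoint),
                             0.02, 0.999))

    def kappa(self, T: float) -> float:
        return kappa_from_s2(self.s2(T))

    def area_scale(self, T: float) -> float:
        slope = self.area_slope_below if T <= self.breakpoint else self.area_slope_above
        return float(max(1.0 + slope * (T - self.breakpoint), 0.5))


@dataclass
class ConstantDisorderModel:
    kappa_value: float = 150.0

    def kappa(self, T: float) -> float:
        return self.kappa_value

    def area_scale(self, T: float) -> float:
        return 1.0


def make_temperature_sweep(spec: SyntheticSpec, T_grid, disorder_model) -> Trajectory:
    """Frames tagged by temperature whose disorder follows ``disorder_model``.

    The lateral structure (and topology) is identical across frames; only
    the tilt disorder and the in-plane box scale change with temperature.
    """
    T_grid = list(T_grid)
    if any(b <= a for a, b in zip(T_grid[:-1], T_grid[1:])):
        raise ValueError("T_grid must be ascending")
    frames = []
    topology = None
    for i, T in enumerate(T_grid):
        spec_t = replace(spec, orientation_kappa=disorder_model.kappa(T))
        sys_t = make_multilayer(spec_t, orientation_key=i)
        s = np.sqrt(disorder_model.area_scale(T))
        xyz = sys_t.frame.coordinates.copy()
        xyz[:, :2] *= s
        box = sys_t.frame.box.copy()
        box[:2] *= s
        frames.append(Frame(xyz, box, tag=float(T)))
        topology = sys_t.topology
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# pseudo-hydrogens for S_CH analysis
# ---------------------------------------------------------------------------

_TETRA_HALF = np.deg2rad(109.47 / 2.0)


def _perpendicular(a: np.ndarray) -> np.ndarray:
    e = np.zeros(3)
    e[np.argmin(np.abs(a))] = 1.0
    v = np.cross(a, e)
    return v / np.linalg.norm(v)


def attach_pseudo_hydrogens(frame: Frame, topology: Topology):
    """Add two pseudo-H per interior chain carbon (bisector construction).

    H positions lie perpendicular to the local chain axis
    (C_{k+1} - C_{k-1}) at the tetrahedral half-angle, with |C-H| = 0.109 nm.
    Returns a new (Topology, Frame) with H rows appended; H beads are named
    ``H<kk>a``/``H<kk>b`` where kk is the 1-based carbon index in its chain.
    """
    df = topology.df
    new_rows, new_coords = [], []
    next_idx = len(df)
    chains = df[
        (~df["is_head"]) & (df["species"] != "WATER")
    ].groupby(["lipid_id", "chain_role"], sort=True)
    for (lid, role), sub in chains:
        rows = topology.chain_indices(lid, role)
        if len(rows) < 3:
            raise ValueError(
                f"chain ({lid}, {role}) has {len(rows)} carbons; need >= 3"
            )
        pos = frame.coordinates[rows]
        sp = sub["species"].iloc[0]
        for k in range(1, len(rows) - 1):
            a = pos[k + 1] - pos[k - 1]
            a = a / np.linalg.norm(a)
            b = (pos[k - 1] - pos[k]) + (pos[k + 1] - pos[k])
            b = b - (b @ a) * a
            nb = np.linalg.norm(b)
            b = b / nb if nb > 1e-9 else _perpendicular(a)
            n = np.cross(a, b)
            for tag, s in (("a", 1.0), ("b", -1.0)):
                h_dir = np.cos(_TETRA_HALF) * b + s * np.sin(_TETRA_HALF) * n
                new_coords.append(pos[k] + CH_BOND_LENGTH * h_dir)
                new_rows.append(
                    [next_idx, lid, sp, role, f"H{k + 1:02d}{tag}", 1.008, False]
                )
                next_idx += 1
    aug = pd.concat(
        [df, pd.DataFrame(new_rows, columns=df.columns)], ignore_index=True
    )
    xyz = np.vstack([frame.coordinates, np.asarray(new_coords)])
    return Topology(aug), Frame(xyz, frame.box, frame.tag)


# ---------------------------------------------------------------------------
# synthetic scattering profiles
# ---------------------------------------------------------------------------

def make_saxd_profile(peaks, q_grid, noise_sd: float = 0.0, seed: int = 0,
                      background: float = 0.0):
    """Sum of Pearson VII peaks + flat background + Gaussian noise.

    ``peaks`` is a list of (q0, amplitude, half-width w, shape m).
    Returns (q, intensity).
    """
    from .scattering import pearson_vii

    q = np.asarray(q_grid, dtype=float)
    if (q <= 0).any() or (np.diff(q) <= 0).any():
        raise ValueError("q_grid must be positive and ascending")
    intensity = np.full_like(q, float(background))
    for q0, amp, w, m in peaks:
        intensity = intensity + pearson_vii(q, q0, amp, w, m)
    if noise_sd > 0:
        intensity = intensity + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=len(q)
        )
    return q, intensity


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_system(outdir, system: SyntheticSystem, stem: str = "system") -> dict:
    """Write GRO + topology CSV + ground-truth JSON; returns the paths."""
    from .io import write_gro, write_topology_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gro": outdir / f"{stem}.gro",
        "topology": outdir / f"{stem}_topology.csv",
        "truth": outdir / f"{stem}_truth.json",
    }
    write_gro(paths["gro"], system.topology, system.frame)
    write_topology_csv(paths["topology"], system.topology)
    paths["truth"].write_text(json.dumps(_jsonable(system.truth), indent=1))
    return paths
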