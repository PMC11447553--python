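"""Structural metrics vs temperature and two-regime transition fitting.

Four metrics track the thermotropic behavior of a multilayer membrane:

* nematic order parameter S2 — largest eigenvalue of the average nematic
  tensor Q = <(3 u u^T - I)/2> of chain directors u, computed per chain
  class over the inner leaflets (S2 = 1: all tails parallel; ~0: isotropic;
  0.8-1 indicates a well-ordered phase, 0.3-0.8 a fluid phase, <0.3
  isotropic);
* carbon-hydrogen order parameter S_CH = (1/2)<3 cos^2 theta - 1> of the
  C-H bond vectors against the bilayer normal, bounded by -0.5
  (perpendicular) and 1 (parallel);
* normalized lipid area NLA — cross-section-weighted tail count per lateral
  area (weights 1 for CER acyl/sphingosine and FFA, 1.9 for CHOL);
* membrane thickness — distance between the half-bulk crossings of the
  water density profile on either side of the stack.

Temperature series are reduced by block averaging (5 °C blocks) and the
order/area trends summarized by a continuous two-segment linear fit with an
exhaustively searched breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .leaflets import LeafletMap, extract_tails
from .model import Frame, Topology, unwrap_chain_xy

#: S2 phase-classification bands
S2_ORDERED_MIN = 0.8
S2_ISOTROPIC_MAX = 0.3

#: cross-sectional area weights for the normalized lipid area
NLA_WEIGHTS = {"CER_acyl": 1.0, "CER_sph": 1.0, "FFA": 1.0, "CHOL": 1.9}

#: default 12-carbon tail section (1-based, inclusive), clamped for short
#: chains; chosen away from the headgroup and the interdigitated chain ends
S2_SECTION = (4, 15)

BLOCK_WIDTH_C = 5.0


# ---------------------------------------------------------------------------
# nematic order parameter
# ---------------------------------------------------------------------------

def chain_director(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a chain section (sign-free director)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("chain section needs >= 2 beads")
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    return vecs[:, -1]


def extract_section(coords: np.ndarray, section=S2_SECTION,
                    warn_short: bool = True) -> np.ndarray:
    """Carbons ``section`` (1-based, inclusive) from the head-proximal end."""
    lo, hi = section
    if len(coords) < hi - lo + 1:
        if warn_short:
            warnings.warn(
                f"chain of {len(coords)} beads shorter than the "
                f"{hi - lo + 1}-carbon section; using the full chain"
            )
        return np.asarray(coords, dtype=float)
    return np.asarray(coords[lo - 1: hi], dtype=float)


def nematic_S2(chains, section=S2_SECTION, warn_short: bool = True) -> float:
    """Largest eigenvalue of the mean nematic tensor of chain directors."""
    chains = list(chains)
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    Q = np.zeros((3, 3))
    warned = False
    for coords in chains:
        sec = extract_section(coords, section, warn_short=warn_short and not warned)
        warned = warned or len(coords) < section[1] - section[0] + 1
        u = chain_director(sec)
        Q += 1.5 * np.outer(u, u) - 0.5 * np.eye(3)
    Q /= len(chains)
    return float(np.linalg.eigvalsh(Q)[-1])


#: chain classes analyzed for S2 (species, chain_role, class name)
S2_CHAIN_CLASSES = (
    ("FFA", "fatty", "FFA"),
    ("CER_NS", "acyl", "CER_acyl"),
    ("CER_NS", "sphingosine", "CER_sph"),
)


def s2_by_class(frame: Frame, topology: Topology, leaflets: LeafletMap,
                section=S2_SECTION, inner_only: bool = True) -> dict:
    """S2 per chain class, computed per leaflet and averaged.

    Chains are grouped into leaflets by their terminal bead; with
    ``inner_only`` the outer (water-facing) leaflets are excluded.
    """
    keep = set(leaflets.inner_leaflets) if inner_only else set(
        range(1, leaflets.n_leaflets + 1)
    )
    per_class_leaflet = {name: {} for _, _, name in S2_CHAIN_CLASSES}
    df = topology.df
    for species, role, name in S2_CHAIN_CLASSES:
        lids = df.loc[
            (df["species"] == species) & (df["chain_role"] == role) & ~df["is_head"],
            "lipid_id",
        ].unique()
        for lid in lids:
            rows = topology.chain_indices(lid, role)
            if len(rows) == 0:
                continue
            leaf = leaflets.leaflet_of(float(frame.coordinates[rows[-1], 2]))
            if leaf not in keep:
                continue
            per_class_leaflet[name].setdefault(leaf, []).append(
                unwrap_chain_xy(frame.coordinates[rows], frame.box)
            )
    out = {}
    for name, by_leaf in per_class_leaflet.items():
        vals = [
            nematic_S2(chains, section=section)
            for chains in by_leaf.values()
            if len(chains) >= 2
        ]
        out[name] = float(np.mean(vals)) if vals else np.nan
    return out


# ---------------------------------------------------------------------------
# C-H order parameter
# ---------------------------------------------------------------------------

def sch_from_vectors(ch_vectors: np.ndarray) -> float:
    """S_CH = (1/2)<3 cos^2 theta - 1> of C-H vectors vs the z axis."""
    v = np.asarray(ch_vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    cos2 = (v[:, 2] / norms) ** 2
    return float(0.5 * np.mean(3.0 * cos2 - 1.0))


def sch_profile(frame: Frame, topology: Topology, species: str,
                chain_role: str) -> pd.Series:
    """Per-carbon S_CH profile of one chain class (pseudo-H required).

    H beads are recognized by the ``H<kk>a/b`` naming convention written by
    the pseudo-hydrogen construction; ``kk`` is the 1-based carbon index.
    """
    df = topology.df
    sel = df[
        (df["species"] == species)
        & (df["chain_role"] == chain_role)
        & df["bead_name"].str.match(r"^H\d\d[ab]$")
    ]
    if sel.empty:
        raise ValueError(f"no pseudo-hydrogens for ({species}, {chain_role})")
    carbon_idx = sel["bead_name"].str[1:3].astype(int)
    vectors = {}
    for (lid, k), sub in sel.groupby([sel["lipid_id"], carbon_idx]):
        rows = topology.chain_indices(lid, chain_role)
        if k > len(rows):
            raise ValueError(f"H beads reference carbon {k} beyond chain length")
        c_pos = frame.coordinates[rows[k - 1]]
        for ridx in sub.index:
            vectors.setdefault(k, []).append(frame.coordinates[ridx] - c_pos)
    ks = sorted(vectors)
    # interior carbons must be contiguous; a gap means a missing H
    if ks != list(range(ks[0], ks[-1] + 1)):
        missing = sorted(set(range(ks[0], ks[-1] + 1)) - set(ks))
        raise ValueError(f"missing pseudo-hydrogens on interior carbons {missing}")
    return pd.Series(
        {k: sch_from_vectors(np.asarray(vectors[k])) for k in ks},
        name=f"S_CH_{species}_{chain_role}",
    ).rename_axis("carbon_index")


# ---------------------------------------------------------------------------
# normalized lipid area and membrane thickness
# ---------------------------------------------------------------------------

def normalized_lipid_area(tail_counts, area: float):
    """NLA = weighted tail count / lateral area; returns (NLA, 1/NLA).

    ``tail_counts`` maps tail type (CER_acyl, CER_sph, CHOL, FFA) to the
    number of tails in one leaflet.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    weighted = sum(NLA_WEIGHTS[t] * n for t, n in tail_counts.items())
    if weighted <= 0:
        raise ValueError("leaflet has no tails")
    nla = weighted / area
    return nla, 1.0 / nla


def central_bilayer_nla(frame: Frame, topology: Topology,
                        leaflets: LeafletMap, tails=None) -> float:
    """Mean NLA of the two central-bilayer leaflets."""
    if tails is None:
        tails = extract_tails(frame, topology, leaflets)
    area = float(frame.box[0] * frame.box[1])
    vals = []
    for leaf in leaflets.central_bilayer:
        counts = {}
        for t in tails:
            if t.leaflet == leaf:
                counts[t.tail_type] = counts.get(t.tail_type, 0) + 1
        vals.append(normalized_lipid_area(counts, area)[0])
    return float(np.mean(vals))


def water_density_profile(frame: Frame, topology: Topology,
                          bin_width: float = 0.1):
    """Water mass density (amu/nm^3) along z; returns (z_centers, density)."""
    mask = (topology.df["species"] == "WATER").to_numpy()
    if not mask.any():
        raise ValueError("no water in system")
    z = frame.coordinates[mask, 2]
    m = topology.masses[mask]
    edges = np.arange(0.0, frame.box[2] + bin_width, bin_width)
    hist, edges = np.histogram(z, bins=edges, weights=m)
    vol = frame.box[0] * frame.box[1] * bin_width
    return 0.5 * (edges[:-1] + edges[1:]), hist / vol


def membrane_thickness(z_centers: np.ndarray, density: np.ndarray,
                       bulk_window: float = 0.5) -> float:
    """Distance between the half-bulk crossings of the water profile.

    The bulk density is the mean over the outermost ``bulk_window`` of each
    water slab.  The inner interface of each slab is located by scanning
    outward from the dry membrane region (the longest zero-density run
    between the slabs) to the first half-bulk crossing, interpolated
    linearly; scanning outward from the membrane makes the crossing robust
    to density fluctuations deep inside the slab.
    """
    z = np.asarray(z_centers, dtype=float)
    rho = np.asarray(density, dtype=float)
    nz = np.flatnonzero(rho > 0)
    if len(nz) == 0:
        raise ValueError("empty water profile")
    bin_w = z[1] - z[0]
    nwin = max(int(round(bulk_window / bin_w)), 1)
    lo_start, hi_end = nz[0], nz[-1]
    # longest zero run between the slabs = the dry membrane region
    runs, cur = [], None
    for i in range(lo_start, hi_end + 1):
        if rho[i] == 0:
            cur = [i, i] if cur is None else [cur[0], i]
        elif cur is not None:
            runs.append(cur)
            cur = None
    if not runs:
        raise ValueError("water on one side only: no dry membrane region found")
    dry_lo, dry_hi = max(runs, key=lambda r: r[1] - r[0])
    bulk_lo = rho[lo_start: lo_start + nwin].mean()
    bulk_hi = rho[hi_end - nwin + 1: hi_end + 1].mean()

    def cross(inner, step, half):
        # walk from the dry region toward the bulk; the first bin at or
        # above half-bulk brackets the interface with its inner neighbor
        i = inner
        while 0 <= i < len(rho) and rho[i] < half:
            i += step
        if not (0 <= i < len(rho)):
            raise ValueError("no half-bulk crossing found")
        j = i - step  # inner neighbor, below half
        f = (rho[i] - half) / (rho[i] - rho[j])
        return z[i] + f * (z[j] - z[i])

    z_lo = cross(dry_lo - 1, -1, bulk_lo / 2.0)
    z_hi = cross(dry_hi + 1, +1, bulk_hi / 2.0)
    if z_hi <= z_lo:
        raise ValueError("interfaces out of order: water on one side only?")
    return float(z_hi - z_lo)


def frame_membrane_thickness(frame: Frame, topology: Topology,
                             bin_width: float = 0.1) -> float:
    z, rho = water_density_profile(frame, topology, bin_width)
    return membrane_thickness(z, rho)


# ---------------------------------------------------------------------------
# block averaging and two-regime fits
# ---------------------------------------------------------------------------

def block_average(temperatures, metrics: pd.DataFrame,
                  block: float = BLOCK_WIDTH_C) -> pd.DataFrame:
    """Mean of each metric over half-open temperature blocks [T0, T0+block).

    Returns a DataFrame indexed by block center with an ``n_frames`` column;
    empty blocks inside the covered range are omitted with a warning.
    """
    T = np.asarray(list(temperatures), dtype=float)
    if len(T) != len(metrics):
        raise ValueError("temperature and metric lengths differ")
    start = np.floor(T.min() / block) * block
    ids = np.floor((T - start) / block).astype(int)
    out = metrics.copy()
    out["_block"] = ids
    g = out.groupby("_block").mean()
    g["n_frames"] = out.groupby("_block").size()
    covered = set(range(ids.min(), ids.max() + 1))
    empty = covered - set(g.index)
    if empty:
        warnings.warn(f"{len(empty)} empty temperature block(s) omitted")
    g.index = start + (g.index + 0.5) * block
    return g.rename_axis("block_T")


@dataclass
class TwoRegimeFit:
    breakpoint: float
    slope_low: float
    slope_high: float
    value_at_break: float
    sse: float
    sse_single: float
    no_transition: bool

    @property
    def improvement(self) -> float:
        return 1.0 - self.sse / self.sse_single if self.sse_single > 0 else 0.0


def two_regime_fit(block_T, values, min_points: int = 3,
                   no_transition_improvement: float = 0.05) -> TwoRegimeFit:
    """Continuous two-segment linear least squares with searched breakpoint.

    Candidate breakpoints are the midpoints between consecutive blocks with
    at least ``min_points`` blocks on each side.  The fit is flagged
    ``no_transition`` when the SSE improvement over a single line is below
    ``no_transition_improvement``.
    """
    T = np.asarray(list(block_T), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if len(T) < 2 * min_points:
        raise ValueError(f"need >= {2 * min_points} blocks, got {len(T)}")
    order = np.argsort(T)
    T, y = T[order], y[order]

    X1 = np.column_stack([np.ones_like(T), T])
    beta1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse_single = float(res1[0]) if len(res1) else float(
        ((y - X1 @ beta1) ** 2).sum()
    )

    best = None
    for i in range(min_points - 1, len(T) - min_points):
        c = 0.5 * (T[i] + T[i + 1])
        dT = T - c
        X = np.column_stack([np.ones_like(T), np.minimum(dT, 0), np.maximum(dT, 0)])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ beta) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, c, beta)
    sse, c, beta = best
    # a single line already at numerical zero SSE is a perfect line: the
    # relative-improvement criterion is meaningless there
    scale = float(np.mean(y**2)) + 1e-300
    single_is_perfect = sse_single / scale < 1e-18
    return TwoRegimeFit(
        breakpoint=float(c),
        slope_low=float(beta[1]),
        slope_high=float(beta[2]),
        value_at_break=float(beta[0]),
        sse=sse,
        sse_single=sse_single,
        no_transition=bool(
            single_is_perfect
            or 1.0 - sse / sse_single < no_transition_improvement
        ),
    )


def classify_s2_phase(s2: float) -> str:
    """Ordered / fluid / isotropic classification of an S2 value."""
    if s2 >= S2_ORDERED_MIN:
        return "ordered"
    if s2 >= S2_ISOTROPIC_MAX:
        return "fluid"
    return "isotropic"


def thermo_series(trajectory, n_leaflets: int = 6,
                  block: float = BLOCK_WIDTH_C) -> pd.DataFrame:
    """Per-frame S2/NLA/thickness reduced to 5 °C blocks (ThermoSeries).

    Frames must carry a temperature tag.  Returns block_T-indexed columns
    S2_FFA, S2_acyl, S2_sph, NLA, NLA_reciprocal, thickness.
    """
    from .leaflets import assign_leaflets

    rows, temps = [], []
    topology = trajectory.topology
    for fr in trajectory.frames:
        if fr.tag is None:
            raise ValueError("frames must be temperature-tagged")
        leaflets = assign_leaflets(fr, topology, n_leaflets)
        tails = extract_tails(fr, topology, leaflets)
        s2 = s2_by_class(fr, topology, leaflets)
        nla = central_bilayer_nla(fr, topology, leaflets, tails=tails)
        rows.append(
            {
                "S2_FFA": s2["FFA"],
                "S2_acyl": s2["CER_acyl"],
                "S2_sph": s2["CER_sph"],
                "NLA": nla,
                "NLA_reciprocal": 1.0 / nla,
                "thickness": frame_membrane_thickness(fr, topology),
            }
        )
        temps.append(fr.tag)
    return block_average(temps, pd.DataFrame(rows), block=block)
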