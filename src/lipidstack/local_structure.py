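"""Grid-based local bilayer thickness and composition of the central bilayer.

Local values are evaluated on a G x G grid across the bilayer plane
(default 50 x 50).  At each grid point the lipids whose center of mass lies
within ``radius`` (default 0.8 nm) in the periodic x-y plane are isolated;
the local thickness is the separation of the two head-bead mass-density
peaks flanking the central-bilayer midplane (0.1 nm histogram bins along z),
and the local composition is the fraction of each of the four tail types
among the isolated central-bilayer tails.  Grid points with too few
contributors, or without two detectable peaks, are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .leaflets import LeafletMap, extract_tails
from .model import Frame, Topology, lipid_com_table

Z_BIN_NM = 0.1
TAIL_TYPE_ORDER = ("CER_acyl", "CER_sph", "CHOL", "FFA")


@dataclass
class GridMap:
    """Lateral map of a local quantity with a validity mask.

    ``values`` has shape (G, G) for thickness (nm) or (G, G, 4) for
    tail-type fractions ordered as TAIL_TYPE_ORDER.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True where valid
    kind: str  # 'thickness' | 'composition'

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def _grid_centers(box, grid_size):
    x = (np.arange(grid_size) + 0.5) * box[0] / grid_size
    y = (np.arange(grid_size) + 0.5) * box[1] / grid_size
    return x, y


def _neighbor_lists(points_xy, box, grid_size, radius):
    """Indices of points within radius of each grid center (periodic x-y)."""
    x, y = _grid_centers(box, grid_size)
    gx, gy = np.meshgrid(x, y, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(np.mod(points_xy, box[:2]), boxsize=box[:2])
    return x, y, tree.query_ball_point(centers, r=radius)


def _peak_position(hist, edges, idx):
    """Mass-weighted centroid of the peak bin and its two neighbors."""
    lo = max(idx - 1, 0)
    hi = min(idx + 2, len(hist))
    w = hist[lo:hi]
    c = 0.5 * (edges[lo:hi] + edges[lo + 1 : hi + 1])
    return float((w * c).sum() / w.sum())


def _local_thickness(head_z, head_m, midplane, z_lo=-np.inf, z_hi=np.inf):
    """Distance between the two density peaks flanking the midplane.

    The peaks are searched within (z_lo, midplane) and (midplane, z_hi) —
    the z territories of the two central leaflets — and on each side the
    dominant local maximum is taken as the head plane, so stray density
    cannot masquerade as a peak.
    """
    if len(head_z) == 0:
        return np.nan
    lo = head_z.min() - Z_BIN_NM
    edges = np.arange(lo, head_z.max() + 2 * Z_BIN_NM, Z_BIN_NM)
    hist, edges = np.histogram(head_z, bins=edges, weights=head_m)
    g = np.r_[-1.0, hist, -1.0]
    peaks = np.flatnonzero((g[1:-1] > 0) & (g[1:-1] >= g[:-2]) & (g[1:-1] > g[2:]))
    if len(peaks) == 0:
        return np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    below = peaks[(centers[peaks] < midplane) & (centers[peaks] > z_lo)]
    above = peaks[(centers[peaks] >= midplane) & (centers[peaks] < z_hi)]
    if len(below) == 0 or len(above) == 0:
        return np.nan
    p_lo = below[np.argmax(hist[below])]
    p_hi = above[np.argmax(hist[above])]
    return _peak_position(hist, edges, p_hi) - _peak_position(hist, edges, p_lo)


def thickness_map(frame: Frame, topology: Topology, leaflets: LeafletMap,
                  grid_size: int = 50, radius: float = 0.8,
                  min_lipids: int = 3) -> GridMap:
    """Local central-bilayer thickness on a periodic G x G grid."""
    if leaflets.central_bilayer is None:
        raise ValueError("no central bilayer identified")
    com = lipid_com_table(frame, topology)
    df = topology.df
    heads = df[df["is_head"] & (df["species"] != "WATER")]
    head_z = frame.coordinates[heads.index.to_numpy(), 2]
    head_m = heads["mass"].to_numpy()
    # per-lipid head bead slices, aligned with com.index
    order = np.argsort(heads["lipid_id"].to_numpy(), kind="stable")
    hz_sorted = head_z[order]
    hm_sorted = head_m[order]
    lids_sorted = heads["lipid_id"].to_numpy()[order]
    starts = np.searchsorted(lids_sorted, com.index.to_numpy(), side="left")
    stops = np.searchsorted(lids_sorted, com.index.to_numpy(), side="right")

    midplane = leaflets.central_midplane
    # z territories of the two central leaflets (watershed basins)
    c_lo, _ = leaflets.central_bilayer
    z_lo = leaflets.boundaries[c_lo - 2] if c_lo >= 2 else -np.inf
    z_hi = (
        leaflets.boundaries[c_lo] if c_lo < len(leaflets.boundaries) else np.inf
    )
    xy = com[["x", "y"]].to_numpy()
    x, y, lists = _neighbor_lists(xy, frame.box, grid_size, radius)
    values = np.full((grid_size, grid_size), np.nan)
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for flat, sel in enumerate(lists):
        i, j = divmod(flat, grid_size)
        if len(sel) < min_lipids:
            continue
        zs = np.concatenate([hz_sorted[starts[s]: stops[s]] for s in sel])
        ms = np.concatenate([hm_sorted[starts[s]: stops[s]] for s in sel])
        t = _local_thickness(zs, ms, midplane, z_lo, z_hi)
        if np.isfinite(t):
            values[i, j] = t
            mask[i, j] = True
    return GridMap(x, y, values, mask, "thickness")


def composition_map(frame: Frame, topology: Topology, leaflets: LeafletMap,
                    grid_size: int = 50, radius: float = 0.8,
                    min_lipids: int = 3, tails=None) -> GridMap:
    """Local tail-type fractions (conformer-agnostic) of the central bilayer."""
    if tails is None:
        tails = extract_tails(frame, topology, leaflets)
    central = set(leaflets.central_bilayer)
    central_tails = [t for t in tails if t.leaflet in central]
    if not central_tails:
        raise ValueError("no tails in the central bilayer")
    xy = np.array([t.com[:2] for t in central_tails])
    types = np.array(
        [TAIL_TYPE_ORDER.index(t.tail_type) for t in central_tails], dtype=int
    )
    x, y, lists = _neighbor_lists(xy, frame.box, grid_size, radius)
    values = np.full((grid_size, grid_size, 4), np.nan)
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for flat, sel in enumerate(lists):
        i, j = divmod(flat, grid_size)
        if len(sel) < min_lipids:
            continue
        counts = np.bincount(types[sel], minlength=4)
        values[i, j] = counts / counts.sum()
        mask[i, j] = True
    return GridMap(x, y, values, mask, "composition")


def thickness_histogram(maps, bin_width: float = 0.05):
    """Pooled histogram of local thickness over frames/replicates.

    Returns a DataFrame with bin_center and count columns.
    """
    vals = np.concatenate([m.valid_values().ravel() for m in maps])
    if len(vals) == 0:
        raise ValueError("no valid grid points")
    lo = np.floor(vals.min() / bin_width) * bin_width
    edges = np.arange(lo, vals.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    hist, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_center": 0.5 * (edges[:-1] + edges[1:]), "count": hist}
    )


def excess_fraction_histograms(maps, reference=None, bin_width: float = 0.01):
    """Per-tail-type histograms of local fraction minus the bilayer average.

    ``reference`` maps tail type to the central-bilayer average fraction; by
    default it is the pooled mean over all valid grid points.  Returns a dict
    tail type -> DataFrame(bin_center, count).
    """
    pooled = np.concatenate(
        [m.values[m.mask].reshape(-1, 4) for m in maps], axis=0
    )
    if reference is None:
        ref = pooled.mean(axis=0)
    else:
        ref = np.array([reference[t] for t in TAIL_TYPE_ORDER])
    out = {}
    for k, ttype in enumerate(TAIL_TYPE_ORDER):
        dev = pooled[:, k] - ref[k]
        lo = np.floor(dev.min() / bin_width) * bin_width
        edges = np.arange(lo, dev.max() + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
        hist, edges = np.histogram(dev, bins=edges)
        out[ttype] = pd.DataFrame(
            {"bin_center": 0.5 * (edges[:-1] + edges[1:]), "count": hist}
        )
    return out


def pooled_points(thickness_maps, composition_maps) -> pd.DataFrame:
    """Join thickness and composition maps into (thickness, 4 fractions) rows.

    Only grid points valid in both maps contribute; this is the input to the
    correlation and mixture-model analyses.
    """
    rows = []
    for tm, cm in zip(thickness_maps, composition_maps):
        m = tm.mask & cm.mask
        block = np.column_stack([tm.values[m], cm.values[m].reshape(-1, 4)])
        rows.append(block)
    data = np.concatenate(rows, axis=0)
    return pd.DataFrame(data, columns=["thickness"] + list(TAIL_TYPE_ORDER))
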