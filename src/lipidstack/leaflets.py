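"""Leaflet detection and CER conformer classification.

Leaflets are located from the distribution of head-bead centroids along the
bilayer normal: a 0.1 nm histogram smoothed with a 3-bin moving average has
one peak per leaflet head plane, and the basins between adjacent peaks
partition z into leaflet territories.  Because head density is zero in the
inter-leaflet gaps, basin boundaries are taken at the midpoint of the
minimum plateau between two peaks, which is deterministic.

A CER NS chain belongs to the leaflet containing its terminal (chain-end)
bead, so an extended ceramide — one chain in the central bilayer, the other
in the adjacent leaflet — is classified by comparing the two termini.
One-chain lipids (CHOL, FFA) are assigned by their head-bead centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    Frame,
    TailInstance,
    Topology,
    head_centroid_z,
    tail_com,
    unwrap_chain_xy,
)

HIST_BIN_NM = 0.1


class LeafletDetectionError(RuntimeError):
    pass


@dataclass
class LeafletMap:
    """Leaflets ordered bottom-to-top (1-based indices).

    ``peak_z`` are head-plane positions, ``boundaries`` the K-1 basin cuts,
    ``pairing`` groups consecutive leaflets into bilayers, and
    ``central_bilayer`` is the middle pair by mean z.
    """

    peak_z: np.ndarray
    boundaries: np.ndarray
    pairing: list
    central_bilayer: tuple

    @property
    def n_leaflets(self) -> int:
        return len(self.peak_z)

    def leaflet_of(self, z):
        """Leaflet index (1..K) of a z position (scalar or array)."""
        idx = np.searchsorted(self.boundaries, z) + 1
        return int(idx) if np.isscalar(z) else idx

    @property
    def central_midplane(self) -> float:
        i, j = self.central_bilayer
        return 0.5 * (self.peak_z[i - 1] + self.peak_z[j - 1])

    @property
    def inner_leaflets(self) -> tuple:
        """All leaflets not in direct contact with bulk water."""
        return tuple(range(2, self.n_leaflets))


def _smooth3(h: np.ndarray) -> np.ndarray:
    out = h.astype(float).copy()
    out[1:-1] = (h[:-2] + h[1:-1] + h[2:]) / 3.0
    return out


def assign_leaflets(frame: Frame, topology: Topology, n_leaflets: int = 6) -> LeafletMap:
    """Detect leaflet head planes by histogram watershed of head-centroid z."""
    if n_leaflets < 2 or n_leaflets % 2:
        raise ValueError("n_leaflets must be even and >= 2")
    z = head_centroid_z(frame, topology).to_numpy()
    if len(z) == 0:
        raise LeafletDetectionError("no non-water lipids present")
    lo, hi = z.min() - HIST_BIN_NM, z.max() + HIST_BIN_NM
    edges = np.arange(lo, hi + HIST_BIN_NM, HIST_BIN_NM)
    hist, edges = np.histogram(z, bins=edges)
    smooth = _smooth3(hist)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # local maxima of the smoothed histogram (plateaus -> leftmost bin kept)
    g = np.r_[-1.0, smooth, -1.0]
    peaks = np.flatnonzero((g[1:-1] > 0) & (g[1:-1] >= g[:-2]) & (g[1:-1] > g[2:]))
    if len(peaks) < n_leaflets:
        # allow flat-topped peaks: also accept strict rises followed by plateau
        peaks = np.flatnonzero((g[1:-1] > 0) & (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:]))
    # greedy selection by height with a minimum separation, so that a head
    # plane split into two close sub-planes (lateral thickness domains)
    # counts as one leaflet band
    min_sep_bins = int(round(0.5 / HIST_BIN_NM))
    chosen = []
    for p in peaks[np.argsort(smooth[peaks])[::-1]]:
        if all(abs(p - c) >= min_sep_bins for c in chosen):
            chosen.append(p)
        if len(chosen) == n_leaflets:
            break
    if len(chosen) < n_leaflets:
        raise LeafletDetectionError(
            f"leaflet detection failed: found {len(chosen)} head-density bands, "
            f"need {n_leaflets}"
        )
    top = np.sort(np.array(chosen))
    # refine each peak position by a mass-weighted centroid of the head
    # centroids inside the peak's own histogram bin +/- one bin
    peak_z = []
    for p in top:
        sel = (z >= centers[p] - 1.5 * HIST_BIN_NM) & (z <= centers[p] + 1.5 * HIST_BIN_NM)
        peak_z.append(z[sel].mean() if sel.any() else centers[p])
    peak_z = np.asarray(peak_z)

    # watershed boundaries: midpoint of the minimal plateau between peaks
    boundaries = []
    for a, b in zip(top[:-1], top[1:]):
        seg = smooth[a : b + 1]
        mn = seg.min()
        idx = np.flatnonzero(seg == mn)
        mid = a + 0.5 * (idx[0] + idx[-1])
        boundaries.append(lo + (mid + 0.5) * HIST_BIN_NM)
    boundaries = np.asarray(boundaries)

    pairing = [(i + 1, i + 2) for i in range(0, n_leaflets, 2)]
    mean_z = [0.5 * (peak_z[i - 1] + peak_z[j - 1]) for i, j in pairing]
    central = pairing[int(np.argsort(mean_z)[(len(pairing) - 1) // 2])]
    if len(pairing) % 2:  # odd number of bilayers: true middle pair
        central = pairing[len(pairing) // 2]
    return LeafletMap(peak_z=peak_z, boundaries=boundaries, pairing=pairing,
                      central_bilayer=central)


def _terminal_bead_z(frame: Frame, topology: Topology, lipid_id: int, role: str) -> float:
    rows = topology.chain_indices(lipid_id, role)
    if len(rows) == 0:
        raise ValueError(f"lipid {lipid_id} has no {role} chain beads")
    return float(frame.coordinates[rows[-1], 2])


def classify_cer_conformer(frame: Frame, topology: Topology, leaflets: LeafletMap,
                           lipid_id: int) -> str:
    """``extended`` if the two CER chain termini lie in different leaflets."""
    za = _terminal_bead_z(frame, topology, lipid_id, "acyl")
    zs = _terminal_bead_z(frame, topology, lipid_id, "sphingosine")
    la, ls = leaflets.leaflet_of(za), leaflets.leaflet_of(zs)
    return "extended" if la != ls else "hairpin"


def extract_tails(frame: Frame, topology: Topology, leaflets: LeafletMap) -> list:
    """All tail instances of a frame with leaflet and conformer labels.

    CER tails are assigned the leaflet of their terminal bead; CHOL and FFA
    the leaflet of their head-bead centroid.
    """
    head_z = head_centroid_z(frame, topology)
    tails = []
    df = topology.df
    for lipid_id, sub in df[df["species"] != "WATER"].groupby("lipid_id", sort=True):
        species = sub["species"].iloc[0]
        if species == "CER_NS":
            conf = classify_cer_conformer(frame, topology, leaflets, lipid_id)
            for role, ttype in (("acyl", "CER_acyl"), ("sphingosine", "CER_sph")):
                rows = topology.chain_indices(lipid_id, role)
                chain = unwrap_chain_xy(frame.coordinates[rows], frame.box)
                com = tail_com(chain, topology.masses[rows])
                zt = frame.coordinates[rows[-1], 2]
                tails.append(TailInstance(lipid_id, ttype, conf,
                                          leaflets.leaflet_of(zt), com))
        else:
            role = "sterol" if species == "CHOL" else "fatty"
            rows = topology.chain_indices(lipid_id, role)
            chain = unwrap_chain_xy(frame.coordinates[rows], frame.box)
            com = tail_com(chain, topology.masses[rows])
            leaf = leaflets.leaflet_of(float(head_z.loc[lipid_id]))
            tails.append(TailInstance(lipid_id, species if species == "CHOL" else "FFA",
                                      "not_applicable", leaf, com))
    return tails
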