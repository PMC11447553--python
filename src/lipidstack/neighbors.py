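"""Nearest-neighbor tail-pair counting against the perfect-mixing null.

Six tail classes are distinguished — the acyl and sphingosine chains of
extended and hairpin CER NS, CHOL, and FFA — forming 21 unordered pair
types.  Each tail contributes its k nearest other tails by 3D minimum-image
center-of-mass distance (k=6, or 7 for CHOL, which has ~7 lateral neighbors
on average); every directed query->neighbor relation increments its
unordered pair bin.  Observed relative pair frequencies are divided by the
combinatorial null of a perfectly mixed system: weight N_i*N_j for unlike
pairs and N(N-1)/2 for like pairs, normalized over the 21 pair types.  The
factor 2 between directed counts and unordered-pair weights cancels in this
ratio, so normalized counts are 1 in a perfectly mixed system (up to the
documented unequal-k approximation for CHOL).
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .model import min_image_displacement

TAIL_CLASSES = (
    "CER_acyl_ext",
    "CER_acyl_hp",
    "CER_sph_ext",
    "CER_sph_hp",
    "CHOL",
    "FFA",
)
#: the 21 unordered pair types
PAIR_TYPES = tuple(combinations_with_replacement(TAIL_CLASSES, 2))

K_DEFAULT = 6
K_CHOL = 7


def tail_class(tail) -> str:
    """Map a TailInstance to one of the six neighbor-analysis classes."""
    if tail.tail_type in ("CHOL", "FFA"):
        return tail.tail_type
    suffix = "ext" if tail.conformer == "extended" else "hp"
    return f"{tail.tail_type}_{suffix}"


def knn_tail_neighbors(tails, box, k: int = K_DEFAULT, k_chol: int = K_CHOL):
    """k nearest other tails per tail (3D periodic COM distance).

    Returns a list of integer index arrays; the query tail's own k is
    ``k_chol`` when its class is CHOL.  Ties are broken by particle index,
    making the result independent of input ordering up to relabeling.
    """
    n = len(tails)
    classes = [tail_class(t) for t in tails]
    ks = np.array([k_chol if c == "CHOL" else k for c in classes])
    if n < ks.max() + 1:
        raise ValueError(f"need at least {ks.max() + 1} tails, got {n}")
    coms = np.array([t.com for t in tails])
    box = np.asarray(box, dtype=float)
    # vectorized minimum-image distance matrix
    d2 = np.zeros((n, n))
    for ax in range(3):
        d = coms[:, ax, None] - coms[None, :, ax]
        d -= box[ax] * np.round(d / box[ax])
        d2 += d * d
    np.fill_diagonal(d2, np.inf)
    # lexicographic (distance, index) order resolves exact ties deterministically
    idx = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx, d2), axis=1)
    return [order[i, : ks[i]].copy() for i in range(n)]


def pair_counts(neighbor_lists, classes) -> pd.Series:
    """Raw directed-edge counts per unordered pair type (21 bins)."""
    cls_id = {c: i for i, c in enumerate(TAIL_CLASSES)}
    ci = np.array([cls_id[c] for c in classes])
    counts = {p: 0 for p in PAIR_TYPES}
    nc = len(TAIL_CLASSES)
    mat = np.zeros((nc, nc), dtype=int)
    for i, nbrs in enumerate(neighbor_lists):
        a = ci[i]
        for b in ci[nbrs]:
            mat[min(a, b), max(a, b)] += 1
    for (a, b), _ in np.ndenumerate(mat):
        if b >= a:
            counts[(TAIL_CLASSES[a], TAIL_CLASSES[b])] = int(mat[a, b])
    return pd.Series(counts, name="raw_count")


def expected_pair_relative_probability(type_counts) -> pd.Series:
    """Perfect-mixing relative pair probabilities from type counts.

    weight(i,j) = N_i * N_j for unlike pairs, N(N-1)/2 for like pairs,
    normalized to sum to 1 over the 21 pair types.
    """
    N = {c: int(type_counts.get(c, 0)) for c in TAIL_CLASSES}
    if sum(N.values()) < 2:
        raise ValueError("need at least 2 tails")
    w = {}
    for a, b in PAIR_TYPES:
        w[(a, b)] = N[a] * (N[a] - 1) / 2.0 if a == b else float(N[a] * N[b])
    total = sum(w.values())
    if total <= 0:
        raise ValueError("degenerate composition: no pair can form")
    return pd.Series({p: v / total for p, v in w.items()}, name="relative_probability")


def normalized_pair_counts(raw: pd.Series, type_counts) -> pd.DataFrame:
    """Observed relative frequency divided by the mixing-null probability."""
    total = raw.sum()
    if total <= 0:
        raise ValueError("total raw count must be > 0")
    rel = expected_pair_relative_probability(type_counts)
    out = pd.DataFrame({"raw_count": raw, "relative_probability": rel})
    out["normalized_count"] = np.where(
        rel > 0, (raw / total) / rel.replace(0, np.nan), np.nan
    )
    return out


def count_tail_pairs(tails, box, k: int = K_DEFAULT, k_chol: int = K_CHOL) -> pd.DataFrame:
    """One-call pipeline: kNN -> raw counts -> normalized counts."""
    classes = [tail_class(t) for t in tails]
    nbrs = knn_tail_neighbors(tails, box, k=k, k_chol=k_chol)
    raw = pair_counts(nbrs, classes)
    type_counts = pd.Series(classes).value_counts().to_dict()
    return normalized_pair_counts(raw, type_counts)


def replicate_pair_table(tables) -> pd.DataFrame:
    """Mean +/- sd of normalized counts over replicates, sorted ascending.

    ``tables`` is an iterable of per-replicate outputs of
    :func:`normalized_pair_counts` (each already a per-replicate average if
    multiple frames were pooled).
    """
    norm = pd.concat([t["normalized_count"] for t in tables], axis=1)
    raw = pd.concat([t["raw_count"] for t in tables], axis=1)
    out = pd.DataFrame(
        {
            "normalized_count_mean": norm.mean(axis=1),
            "normalized_count_sd": norm.std(axis=1, ddof=1),
            "raw_count_mean": raw.mean(axis=1),
        }
    )
    out = out.sort_values("normalized_count_mean")
    out.insert(0, "tail_1", [p[0] for p in out.index])
    out.insert(1, "tail_2", [p[1] for p in out.index])
    return out.reset_index(drop=True)


def coordination_numbers(neighbor_lists, classes, k: int = K_DEFAULT,
                         k_chol: int = K_CHOL) -> pd.DataFrame:
    """Composition-normalized coordination numbers.

    Entry (reference i, neighbor j) is the mean number of type-j tails among
    a type-i tail's k neighbors divided by the mixed-null expectation
    k * N_j' / (N - 1) with N_j' = N_j - delta_ij; 1 means no preference.
    Reference types with no tails are omitted.
    """
    classes = list(classes)
    n = len(classes)
    cls_id = {c: i for i, c in enumerate(TAIL_CLASSES)}
    ci = np.array([cls_id[c] for c in classes])
    Nj = np.bincount(ci, minlength=len(TAIL_CLASSES))
    rows = {}
    for ref_id, ref in enumerate(TAIL_CLASSES):
        members = np.flatnonzero(ci == ref_id)
        if len(members) == 0:
            continue
        k_ref = k_chol if ref == "CHOL" else k
        counts = np.zeros(len(TAIL_CLASSES))
        for i in members:
            counts += np.bincount(ci[neighbor_lists[i]], minlength=len(TAIL_CLASSES))
        mean_counts = counts / len(members)
        expected = k_ref * (Nj - (np.arange(len(TAIL_CLASSES)) == ref_id)) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[ref] = np.where(expected > 0, mean_counts / expected, np.nan)
    return pd.DataFrame(rows, index=list(TAIL_CLASSES)).T
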