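"""Neighbor-pair counting, the combinatorial mixing null, coordination numbers."""

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidstack.model import TailInstance
from lipidstack.neighbors import (
    PAIR_TYPES,
    TAIL_CLASSES,
    coordination_numbers,
    count_tail_pairs,
    expected_pair_relative_probability,
    knn_tail_neighbors,
    normalized_pair_counts,
    pair_counts,
    tail_class,
)
from lipidstack.synthetic import make_mixed_central_bilayer, mixed_tail_composition

BIG_BOX = np.array([1000.0, 1000.0, 1000.0])


def _tail(i, ttype, xyz, conf=None):
    if conf is None:
        conf = "not_applicable" if ttype in ("CHOL", "FFA") else "hairpin"
    return TailInstance(i, ttype, conf, 1, np.asarray(xyz, dtype=float))


def test_six_classes_form_21_pairs():
    """6 tail types -> 21 unordered pairs (enumeration oracle)."""
    assert len(TAIL_CLASSES) == 6
    oracle = set(combinations_with_replacement(sorted(TAIL_CLASSES), 2))
    assert len(PAIR_TYPES) == 21
    assert {tuple(sorted(p)) for p in PAIR_TYPES} == oracle


class TestKnn:
    def test_line_end_query(self):
        tails = [_tail(i, "FFA", (float(i), 0, 0)) for i in range(8)]
        nbrs = knn_tail_neighbors(tails, BIG_BOX)
        assert sorted(nbrs[0]) == [1, 2, 3, 4, 5, 6]

    def test_hexagon_ring(self):
        center = _tail(0, "FFA", (0, 0, 0))
        ring = [
            _tail(1 + k, "FFA",
                  (np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0))
            for k in range(6)
        ]
        far = [_tail(7 + k, "FFA", (5.0 + k, 5.0, 0.0)) for k in range(3)]
        nbrs = knn_tail_neighbors([center] + ring + far, BIG_BOX)
        assert sorted(nbrs[0]) == [1, 2, 3, 4, 5, 6]

    def test_chol_gets_seven(self):
        tails = [_tail(0, "CHOL", (0, 0, 0))] + [
            _tail(1 + k, "FFA", (0.5 * (k + 1), 0, 0)) for k in range(9)
        ]
        nbrs = knn_tail_neighbors(tails, BIG_BOX)
        assert len(nbrs[0]) == 7
        assert all(len(nbrs[i]) == 6 for i in range(1, 10))

    def test_too_few_tails_errors(self):
        tails = [_tail(i, "FFA", (float(i), 0, 0)) for i in range(4)]
        with pytest.raises(ValueError, match="at least"):
            knn_tail_neighbors(tails, BIG_BOX)

    def test_matches_brute_force(self):
        """Vectorized kNN equals a python-loop O(n^2) oracle (n=150)."""
        rng = np.random.default_rng(8)
        box = np.array([12.0, 12.0, 12.0])
        classes = rng.choice(TAIL_CLASSES, 150)
        tails = []
        for i, cls in enumerate(classes):
            ttype = ("CHOL" if cls == "CHOL" else "FFA" if cls == "FFA"
                     else ("CER_acyl" if "acyl" in cls else "CER_sph"))
            conf = ("not_applicable" if ttype in ("CHOL", "FFA")
                    else ("extended" if cls.endswith("ext") else "hairpin"))
            tails.append(_tail(i, ttype, rng.random(3) * box, conf))
        fast = knn_tail_neighbors(tails, box)
        for i, t in enumerate(tails):
            dists = []
            for j, u in enumerate(tails):
                if i == j:
                    continue
                d = t.com - u.com
                d -= box * np.round(d / box)
                dists.append((float(d @ d), j))
            dists.sort()
            k = 7 if tail_class(t) == "CHOL" else 6
            assert list(fast[i]) == [j for _, j in dists[:k]]


class TestPairCounts:
    def test_mutual_pair_directed_convention(self):
        """Two mutually nearest tails with k=1 contribute a count of 2."""
        tails = [_tail(0, "CER_acyl", (0, 0, 0)), _tail(1, "FFA", (0.5, 0, 0))]
        nbrs = knn_tail_neighbors(tails, BIG_BOX, k=1, k_chol=1)
        raw = pair_counts(nbrs, [tail_class(t) for t in tails])
        assert raw[("CER_acyl_hp", "FFA")] == 2
        assert raw.sum() == 2

    def test_single_type_totals(self):
        tails = [_tail(i, "FFA", (0.4 * i, 0, 0)) for i in range(20)]
        nbrs = knn_tail_neighbors(tails, BIG_BOX)
        raw = pair_counts(nbrs, ["FFA"] * 20)
        assert raw[("FFA", "FFA")] == 6 * 20
        assert raw.sum() == 6 * 20

    def test_total_equals_sum_of_k(self):
        comp = mixed_tail_composition()
        tails, box = make_mixed_central_bilayer(300, comp, seed=4)
        classes = [tail_class(t) for t in tails]
        nbrs = knn_tail_neighbors(tails, box)
        raw = pair_counts(nbrs, classes)
        n_chol = classes.count("CHOL")
        assert raw.sum() == 6 * (300 - n_chol) + 7 * n_chol


class TestMixingNull:
    def test_two_by_two_enumeration(self):
        """N={A:2,B:2}: weights AA=1, AB=4, BB=1 -> relative AB = 4/6."""
        rel = expected_pair_relative_probability({"FFA": 2, "CHOL": 2})
        assert rel[("CHOL", "FFA")] == pytest.approx(4 / 6)
        assert rel[("FFA", "FFA")] == pytest.approx(1 / 6)
        assert rel[("CHOL", "CHOL")] == pytest.approx(1 / 6)

    def test_single_type(self):
        rel = expected_pair_relative_probability({"FFA": 10})
        assert rel[("FFA", "FFA")] == 1.0

    def test_one_of_each(self):
        rel = expected_pair_relative_probability({"FFA": 1, "CHOL": 1})
        assert rel[("CHOL", "FFA")] == 1.0
        assert rel[("FFA", "FFA")] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=6, max_size=6))
    def test_probabilities_sum_to_one(self, counts):
        if sum(counts) < 2:
            return
        rel = expected_pair_relative_probability(dict(zip(TAIL_CLASSES, counts)))
        assert rel.sum() == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_mixed_calibration(self):
        """Normalized counts match the analytic mixed-system expectation.

        With directed counting and k=7 for CHOL, pairs involving CHOL are
        inflated by 13/12 (cross) and 7/6 (self) relative to the equal-k
        value 1/cbar, cbar = 1 + N_CHOL/(6N).  The grand mean stays at 1.
        """
        comp = mixed_tail_composition((1.0, 0.5, 1.0), 0.35)
        tables = [
            count_tail_pairs(*make_mixed_central_bilayer(600, comp, seed=s))
            for s in range(20)
        ]
        norm = pd.concat([t["normalized_count"] for t in tables], axis=1)
        mean = norm.mean(axis=1)
        n_chol = 600 * comp["CHOL"]
        cbar = 1 + n_chol / (6 * 600)
        well_sampled = [
            p for p in mean.index
            if min(comp[p[0]], comp[p[1]]) >= 0.14
        ]
        for p in well_sampled:
            if p == ("CHOL", "CHOL"):
                expect = (7 / 6) / cbar
            elif "CHOL" in p:
                expect = (13 / 12) / cbar
            else:
                expect = 1 / cbar
            assert mean[p] == pytest.approx(expect, abs=0.06), p
        assert mean.mean() == pytest.approx(1.0, abs=0.05)

    def test_segregated_half_planes(self):
        """Full segregation: same-type normalized > 1, cross-type < 1."""
        rng = np.random.default_rng(2)
        tails = []
        for i in range(50):
            tails.append(_tail(i, "FFA", (rng.random() * 5, rng.random() * 10, 0)))
        for i in range(50, 100):
            tails.append(_tail(i, "CER_acyl",
                               (5 + rng.random() * 5, rng.random() * 10, 0)))
        box = np.array([10.0, 10.0, 5.0])
        table = count_tail_pairs(tails, box)
        assert table.loc[("FFA", "FFA"), "normalized_count"] > 1.2
        assert table.loc[("CER_acyl_hp", "CER_acyl_hp"), "normalized_count"] > 1.2
        assert table.loc[("CER_acyl_hp", "FFA"), "normalized_count"] < 0.8

    def test_hairpin_adjacency_inflates_acyl_sph(self, default_system,
                                                 default_leaflets):
        """Hairpin CER chains are laterally paired, so the hairpin
        acyl-sphingosine pair is the most enriched CER pair."""
        from lipidstack.leaflets import extract_tails

        tails = [
            t for t in extract_tails(default_system.frame,
                                     default_system.topology, default_leaflets)
            if t.leaflet in default_leaflets.central_bilayer
        ]
        table = count_tail_pairs(tails, default_system.frame.box)
        hp_pair = table.loc[("CER_acyl_hp", "CER_sph_hp"), "normalized_count"]
        assert hp_pair > 1.1
        # and it exceeds the extended acyl-sph pair (no forced adjacency)
        assert hp_pair > table.loc[("CER_acyl_ext", "CER_sph_ext"),
                                   "normalized_count"]


class TestCoordinationNumbers:
    def test_mixed_system_near_one(self):
        comp = mixed_tail_composition((1.0, 0.5, 1.0), 0.35)
        mats = []
        for s in range(10):
            tails, box = make_mixed_central_bilayer(600, comp, seed=100 + s)
            classes = [tail_class(t) for t in tails]
            nbrs = knn_tail_neighbors(tails, box)
            mats.append(coordination_numbers(nbrs, classes))
        mean = sum(mats) / len(mats)
        assert np.nanmax(np.abs(mean.to_numpy() - 1.0)) < 0.15

    def test_single_type_self_entry(self):
        tails = [_tail(i, "FFA", (0.45 * i, 0, 0)) for i in range(30)]
        nbrs = knn_tail_neighbors(tails, BIG_BOX)
        table = coordination_numbers(nbrs, ["FFA"] * 30)
        assert table.loc["FFA", "FFA"] == pytest.approx(1.0)
        assert len(table) == 1  # absent reference types omitted

    def test_rank_agreement_with_pair_counts(self, default_system,
                                             default_leaflets):
        """Coordination numbers rank pairs like the normalized pair counts."""
        from scipy.stats import spearmanr

        from lipidstack.leaflets import extract_tails

        tails = [
            t for t in extract_tails(default_system.frame,
                                     default_system.topology, default_leaflets)
            if t.leaflet in default_leaflets.central_bilayer
        ]
        classes = [tail_class(t) for t in tails]
        nbrs = knn_tail_neighbors(tails, default_system.frame.box)
        pair_table = normalized_pair_counts(
            pair_counts(nbrs, classes),
            pd.Series(classes).value_counts().to_dict(),
        )
        coord = coordination_numbers(nbrs, classes)
        a, b = [], []
        for (t1, t2), row in pair_table.iterrows():
            if np.isnan(row["normalized_count"]):
                continue
            a.append(row["normalized_count"])
            b.append(0.5 * (coord.loc[t1, t2] + coord.loc[t2, t1]))
        rho = spearmanr(a, b).statistic
        assert rho > 0.8


def test_duplication_invariance():
    """Doubling the system (tails and box) leaves normalized counts stable."""
    comp = mixed_tail_composition()
    tails, box = make_mixed_central_bilayer(400, comp, seed=6)
    t1 = count_tail_pairs(tails, box)
    shifted = [
        TailInstance(t.lipid_id + 1000, t.tail_type, t.conformer, t.leaflet,
                     t.com + np.array([box[0], 0, 0]))
        for t in tails
    ]
    box2 = np.array([2 * box[0], box[1], box[2]])
    t2 = count_tail_pairs(tails + shifted, box2)
    d = (t1["normalized_count"] - t2["normalized_count"]).abs()
    assert d.max() < 0.12
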