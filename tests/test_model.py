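"""Data model, I/O round-trips, leaflet detection, conformer classification."""

import numpy as np
import pandas as pd
import pytest

from lipidstack.io import (
    load_system,
    read_native,
    write_gro,
    write_native,
    write_topology_csv,
)
from lipidstack.leaflets import (
    LeafletDetectionError,
    assign_leaflets,
    classify_cer_conformer,
    extract_tails,
)
from lipidstack.model import (
    Frame,
    Topology,
    TopologyError,
    pbc_xy_distance,
    tail_com,
)


def _toy_topology(rows):
    return Topology(
        pd.DataFrame(
            rows,
            columns=[
                "particle_index", "lipid_id", "species", "chain_role",
                "bead_name", "mass", "is_head",
            ],
        )
    )


def _ffa(lipid_id, first_index):
    """Minimal valid FFA lipid: HEAD + three tail beads."""
    rows = [[first_index, lipid_id, "FFA", "none", "HEAD", 59.0, True]]
    for j in range(3):
        rows.append(
            [first_index + 1 + j, lipid_id, "FFA", "fatty", f"FFA{j+1}", 56.0, False]
        )
    return rows


class TestTopologyValidation:
    def test_unknown_species_rejected(self):
        rows = _ffa(0, 0)
        rows[0][2] = rows[1][2] = rows[2][2] = rows[3][2] = "PHOSPHOLIPID"
        with pytest.raises(TopologyError, match="unknown species"):
            _toy_topology(rows)

    def test_headless_lipid_rejected(self):
        rows = _ffa(0, 0)[1:]  # drop the HEAD bead
        with pytest.raises(TopologyError, match="head"):
            _toy_topology(rows)

    def test_cer_missing_chain_rejected(self):
        rows = [
            [0, 0, "CER_NS", "none", "MHEAD2", 72.0, True],
            [1, 0, "CER_NS", "acyl", "ACL1", 56.0, False],
        ]
        with pytest.raises(TopologyError, match="chain role"):
            _toy_topology(rows)


class TestGeometry:
    def test_tail_com_equal_masses(self):
        com = tail_com(np.array([[0, 0, 1.0], [0, 0, 3.0]]), np.array([1.0, 1.0]))
        assert com[2] == pytest.approx(2.0)

    def test_tail_com_weighted(self):
        com = tail_com(np.array([[0.0, 0, 0], [3.0, 0, 0]]), np.array([2.0, 1.0]))
        assert np.allclose(com, [1.0, 0.0, 0.0])

    def test_tail_com_zero_mass_errors(self):
        with pytest.raises(ValueError):
            tail_com(np.zeros((0, 3)), np.array([]))

    @pytest.mark.parametrize(
        "a,b,box,expect",
        [
            ((0.0, 0.0), (9.5, 0.0), (10.0, 10.0), 0.5),
            ((1.0, 2.0), (1.0, 2.0), (7.0, 7.0), 0.0),
            ((1.0, 1.0), (4.0, 5.0), (100.0, 100.0), 5.0),
        ],
    )
    def test_pbc_xy_distance(self, a, b, box, expect):
        assert pbc_xy_distance(a, b, box) == pytest.approx(expect)

    def test_chol_com_excludes_head_bead(self, default_system):
        """CHOL tail COM is computed from non-head beads only."""
        topo, frame = default_system.topology, default_system.frame
        df = topo.df
        chol_ids = df.loc[df["species"] == "CHOL", "lipid_id"].unique()
        lid = chol_ids[0]
        rows = topo.chain_indices(lid, "sterol")
        names = df.loc[rows, "bead_name"]
        assert "CHEAD" not in set(names)
        com = tail_com(frame.coordinates[rows], topo.masses[rows])
        head_row = df.index[(df["lipid_id"] == lid) & df["is_head"]][0]
        assert not np.allclose(com, frame.coordinates[head_row])


class TestIO:
    def test_toy_identity_roundtrip(self, tmp_path):
        """3-bead toy written and reloaded is a 1-frame, 3-particle system."""
        rows = [
            [0, 0, "FFA", "none", "HEAD", 59.0, True],
            [1, 0, "FFA", "fatty", "FFA1", 56.0, False],
            [2, 0, "FFA", "fatty", "FFA2", 56.0, False],
        ]
        topo = _toy_topology(rows)
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.5], [1.0, 1.0, 2.0]]),
                      np.array([5.0, 5.0, 5.0]))
        write_gro(tmp_path / "toy.gro", topo, frame)
        write_topology_csv(tmp_path / "toy.csv", topo)
        topo2, traj = load_system(tmp_path / "toy.gro", tmp_path / "toy.csv")
        assert len(traj) == 1
        assert topo2.n_particles == 3
        assert np.allclose(traj.frames[0].coordinates, frame.coordinates, atol=1e-3)

    def test_synthetic_gro_roundtrip(self, small_system, tmp_path):
        """Write -> read preserves coordinates to GRO precision (0.001 nm)."""
        write_gro(tmp_path / "s.gro", small_system.topology, small_system.frame)
        write_topology_csv(tmp_path / "s.csv", small_system.topology)
        _, traj = load_system(tmp_path / "s.gro", tmp_path / "s.csv")
        assert np.allclose(
            traj.frames[0].coordinates, small_system.frame.coordinates, atol=1.5e-3
        )
        assert np.allclose(traj.frames[0].box, small_system.frame.box, atol=1e-3)

    def test_count_mismatch_reported(self, tmp_path):
        rows = _ffa(0, 0) + _ffa(1, 4)  # 8 particles
        topo = _toy_topology(rows)
        frame = Frame(np.random.default_rng(0).random((8, 3)) + 0.5,
                      np.array([5.0, 5.0, 5.0]))
        write_gro(tmp_path / "m.gro", topo, frame)
        write_topology_csv(tmp_path / "m.csv", _toy_topology(_ffa(0, 0)))
        with pytest.raises(ValueError, match="4 vs 8"):
            load_system(tmp_path / "m.gro", tmp_path / "m.csv")

    def test_native_container_roundtrip(self, small_system, tmp_path):
        frames = [small_system.frame, Frame(small_system.frame.coordinates + 0.1,
                                            small_system.frame.box, tag=45.0)]
        write_native(tmp_path / "s.h5", small_system.topology, frames)
        topo2, traj = read_native(tmp_path / "s.h5")
        assert len(traj) == 2
        assert traj.frames[1].tag == 45.0
        assert np.allclose(traj.frames[0].coordinates,
                           small_system.frame.coordinates)
        pd.testing.assert_frame_equal(topo2.df, small_system.topology.df)


def _plane_system(plane_z, lipids_per_plane=40, box=(6.0, 6.0, 20.0), seed=0):
    """FFA lipids with head planes at given z positions (tails inward)."""
    rng = np.random.default_rng(seed)
    rows, coords = [], []
    idx = lid = 0
    for k, zp in enumerate(plane_z):
        inward = 1.0 if k % 2 == 0 else -1.0
        for _ in range(lipids_per_plane):
            x, y = rng.random(2) * box[0]
            rows += _ffa(lid, idx)
            coords.append([x, y, zp + rng.normal(0, 0.02)])
            for j in range(1, 4):
                coords.append([x, y, zp + inward * 0.47 * j])
            idx += 4
            lid += 1
    topo = _toy_topology(rows)
    return topo, Frame(np.array(coords), np.array(box))


class TestLeaflets:
    def test_six_constructed_planes(self):
        planes = [0.5, 5.7, 6.5, 11.7, 12.5, 17.7]
        topo, frame = _plane_system(planes)
        lm = assign_leaflets(frame, topo, 6)
        assert lm.n_leaflets == 6
        assert np.allclose(lm.peak_z, planes, atol=0.06)
        assert lm.central_bilayer == (3, 4)

    def test_single_bilayer(self):
        topo, frame = _plane_system([0.2, 5.2])
        lm = assign_leaflets(frame, topo, 2)
        assert lm.n_leaflets == 2
        assert lm.central_bilayer == (1, 2)

    def test_degenerate_single_plane_errors(self):
        topo, frame = _plane_system([5.0])
        with pytest.raises(LeafletDetectionError, match="leaflet detection failed"):
            assign_leaflets(frame, topo, 6)

    def test_permutation_invariance(self, small_system):
        """Leaflet peaks do not depend on particle ordering."""
        topo, frame = small_system.topology, small_system.frame
        lm = assign_leaflets(frame, topo, 6)
        rng = np.random.default_rng(1)
        perm = rng.permutation(topo.n_particles)
        df = topo.df.iloc[perm].copy()
        df["particle_index"] = np.arange(len(df))
        topo2 = Topology(df.reset_index(drop=True))
        lm2 = assign_leaflets(Frame(frame.coordinates[perm], frame.box), topo2, 6)
        assert np.allclose(lm.peak_z, lm2.peak_z, atol=1e-9)

    def test_synthetic_planes_match_truth(self, default_system, default_leaflets):
        truth = np.asarray(default_system.truth["head_planes"])
        assert np.allclose(default_leaflets.peak_z, truth, atol=0.05)


def _cer_rows(lipid_id, first_index):
    rows = []
    i = first_index
    for bname, bmass in (("MHEAD2", 72.0), ("AMIDE", 58.0), ("OH1", 17.0),
                         ("OH2", 17.0)):
        rows.append([i, lipid_id, "CER_NS", "none", bname, bmass, True])
        i += 1
    for j in range(3):
        rows.append([i, lipid_id, "CER_NS", "acyl", f"ACL{j+1}", 56.0, False])
        i += 1
    for j in range(2):
        rows.append([i, lipid_id, "CER_NS", "sphingosine", f"SPH{j+1}", 56.0, False])
        i += 1
    return rows


class TestConformerClassification:
    @pytest.fixture()
    def stack_with_cer(self):
        """Six-plane FFA scaffold + one CER whose chains we position."""
        planes = [0.5, 5.7, 6.5, 11.7, 12.5, 17.7]
        topo, frame = _plane_system(planes)
        n = topo.n_particles

        def with_cer(acyl_dz, sph_dz):
            # CER head at the leaflet-3 plane (z=6.5)
            rows = topo.df.values.tolist() + _cer_rows(9999, n)
            coords = list(frame.coordinates)
            coords += [[3.0, 3.0, 6.5]] * 4  # head beads
            coords += [[3.0, 3.0, 6.5 + acyl_dz * j] for j in (1, 2, 3)]
            coords += [[3.1, 3.0, 6.5 + sph_dz * j] for j in (1, 2)]
            t = Topology(pd.DataFrame(
                rows, columns=list(topo.df.columns)))
            return t, Frame(np.array(coords), frame.box)

        return with_cer

    def test_hairpin_same_leaflet(self, stack_with_cer):
        topo, frame = stack_with_cer(0.47, 0.47)  # both chains up into leaflet 3
        lm = assign_leaflets(frame, topo, 6)
        assert classify_cer_conformer(frame, topo, lm, 9999) == "hairpin"

    def test_extended_adjacent_leaflets(self, stack_with_cer):
        """One tail in the central bilayer, the other in the adjacent leaflet."""
        topo, frame = stack_with_cer(0.47, -0.47)  # sph down into leaflet 2
        lm = assign_leaflets(frame, topo, 6)
        assert classify_cer_conformer(frame, topo, lm, 9999) == "extended"
        tails = {t.tail_type: t for t in extract_tails(frame, topo, lm)
                 if t.lipid_id == 9999}
        assert tails["CER_acyl"].leaflet == 3
        assert tails["CER_sph"].leaflet == 2

    def test_generator_fraction_recovered(self, default_system, default_leaflets):
        """Classifier recovers the imposed extended fraction on 2000 lipids."""
        sys_ = default_system
        tails = extract_tails(sys_.frame, sys_.topology, default_leaflets)
        truth = dict(zip(sys_.truth["lipids"]["lipid_id"],
                         sys_.truth["lipids"]["conformer"]))
        seen = {}
        for t in tails:
            if t.tail_type in ("CER_acyl", "CER_sph"):
                seen.setdefault(t.lipid_id, t.conformer)
        # exact agreement with generator labels
        mismatch = [lid for lid, c in seen.items() if truth[lid] != c]
        assert mismatch == []
        # extended fraction among interior-leaflet CERs (outer-leaflet CERs
        # face water and are always hairpin) recovers the imposed 0.35
        lipdf = sys_.truth["lipids"]
        eligible = lipdf[
            (lipdf["species"] == "CER_NS")
            & lipdf["home_leaflet"].between(2, 5)
        ]["lipid_id"]
        frac = np.mean([seen[lid] == "extended" for lid in eligible])
        assert frac == pytest.approx(
            sys_.truth["fraction_extended_realized"], abs=1e-9
        )
        assert frac == pytest.approx(0.35, abs=0.02)
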