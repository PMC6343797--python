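"""Contact frequencies, accumulated maps, key residues and Shrake–Rupley ASA."""

import numpy as np
import pandas as pd
import pytest

from igg_allostery import contacts, synthetic
from igg_allostery.contacts import (
    ContactFrequencyTable,
    accumulated_contact_map,
    asa,
    contact_frequency,
    key_binding_residues,
)
from igg_allostery.errors import ConfigurationError

rng = np.random.default_rng(7)


def brute_force_pairs(traj, group_a, group_b, cutoff, heavy_only=True):
    """O(N²) oracle: residue pairs in contact per frame."""
    top = traj.topology
    res_idx, res_keys = top.residue_index()
    heavy = top.heavy_mask()
    out = []
    for f in range(traj.n_frames):
        seen = set()
        for i in group_a:
            if heavy_only and not heavy[i]:
                continue
            for j in group_b:
                if heavy_only and not heavy[j]:
                    continue
                if np.linalg.norm(traj.coordinates[f, i] - traj.coordinates[f, j]) <= cutoff:
                    seen.add((int(top.residue_ids[i]), int(top.residue_ids[j])))
        out.append(seen)
    return out


class TestContactFrequency:
    def _fixture(self):
        # 2 residues per group, 4 frames; pair (1, 3) touches in all frames,
        # pair (2, 4) in half
        coords = np.zeros((4, 4, 3))
        coords[:, 0] = [0, 0, 0]
        coords[:, 1] = [0, 20, 0]
        coords[:, 2] = [2, 0, 0]
        coords[2:, 3] = [2, 20, 0]
        coords[:2, 3] = [30, 20, 0]
        from conftest import toy_trajectory

        return toy_trajectory(coords, resids=[1, 2, 3, 4])

    def test_always_within_cutoff(self):
        traj = self._fixture()
        t = contact_frequency(traj, np.array([0, 1]), np.array([2, 3]), 3.0)
        assert t.table.set_index(["resid_a", "resid_b"]).loc[(1, 3), "frequency"] == 1.0

    def test_half_frames(self):
        traj = self._fixture()
        t = contact_frequency(traj, np.array([0, 1]), np.array([2, 3]), 3.0)
        assert t.table.set_index(["resid_a", "resid_b"]).loc[(2, 4), "frequency"] == 0.5

    def test_overlapping_groups_rejected(self):
        traj = self._fixture()
        with pytest.raises(ConfigurationError):
            contact_frequency(traj, np.array([0, 1]), np.array([1, 2]), 3.0)

    def test_matches_brute_force_oracle(self, make_toy):
        coords = rng.uniform(0, 15, size=(10, 50, 3))
        traj = make_toy(coords, resids=list(np.repeat(np.arange(1, 11), 5)))
        a, b = np.arange(25), np.arange(25, 50)
        ours = contact_frequency(traj, a, b, 4.0)
        oracle = brute_force_pairs(traj, a, b, 4.0)
        counts: dict = {}
        for frame_pairs in oracle:
            for p in frame_pairs:
                counts[p] = counts.get(p, 0) + 1
        expected = {p: c / 10 for p, c in counts.items()}
        got = {
            (int(r.resid_a), int(r.resid_b)): r.frequency
            for r in ours.table.itertuples(index=False)
        }
        assert got == pytest.approx(expected)

    def test_monotone_in_cutoff(self, make_toy):
        coords = rng.uniform(0, 10, size=(5, 20, 3))
        traj = make_toy(coords, resids=list(np.repeat(np.arange(1, 5), 5)))
        a, b = np.arange(10), np.arange(10, 20)
        freqs = []
        for cutoff in (2.0, 4.0, 6.0):
            t = contact_frequency(traj, a, b, cutoff)
            freqs.append(t.table["frequency"].sum())
        assert freqs == sorted(freqs)


class TestAccumulatedMap:
    def test_single_touching_pair(self, make_toy):
        traj = make_toy([[0, 0, 0], [1, 0, 0]], resids=[1, 2])
        counts, *_ , n = accumulated_contact_map(traj, np.array([0]), np.array([1]), 3.0)
        assert counts.tolist() == [[1]]
        assert n == 1

    def test_additive_over_frame_ranges(self, make_toy):
        coords = rng.uniform(0, 8, size=(10, 10, 3))
        traj = make_toy(coords, resids=list(np.repeat(np.arange(1, 6), 2)))
        a, b = np.arange(4), np.arange(4, 10)
        c_all, *_ = accumulated_contact_map(traj, a, b, 3.0, (0, 10))
        c_1, *_ = accumulated_contact_map(traj, a, b, 3.0, (0, 4))
        c_2, *_ = accumulated_contact_map(traj, a, b, 3.0, (4, 10))
        np.testing.assert_array_equal(c_all, c_1 + c_2)

    def test_consistent_with_frequency(self, make_toy):
        coords = rng.uniform(0, 8, size=(7, 10, 3))
        traj = make_toy(coords, resids=list(np.repeat(np.arange(1, 6), 2)))
        a, b = np.arange(4), np.arange(4, 10)
        counts, resids_a, _, resids_b, _, n = accumulated_contact_map(traj, a, b, 3.0)
        t = contact_frequency(traj, a, b, 3.0)
        for r in t.table.itertuples(index=False):
            i, j = resids_a.index(r.resid_a), resids_b.index(r.resid_b)
            assert counts[i, j] == pytest.approx(r.frequency * n)


class TestKeyBindingResidues:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["resid_a", "resname_a", "resid_b", "resname_b",
                                         "frequency"])
        return ContactFrequencyTable(df, cutoff=3.0, frame_range=(0, 100))

    def test_top_pair_included(self):
        t = self._table([(1455, "HIS", 479, "ASP", 0.964), (7, "GLY", 8, "ALA", 0.1)])
        assert key_binding_residues(t, 0.2) == {1455, 479}

    def test_all_below_threshold_empty(self):
        t = self._table([(1, "A", 2, "B", 0.1)])
        assert key_binding_residues(t, 0.2) == set()

    def test_strict_inequality_at_boundary(self):
        t = self._table([(1, "A", 2, "B", 0.2)])
        assert key_binding_residues(t, 0.2) == set()
        assert key_binding_residues(t, 0.2 - 1e-9) == {1, 2}


class TestAsa:
    def test_isolated_sphere_closed_form(self, make_toy):
        traj = make_toy([[0.0, 0.0, 0.0]])  # carbon, r = 1.7
        total, _ = asa(traj, probe_radius=1.4, n_sphere_points=960)
        assert total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_fully_enclosed_atom_zero(self, make_toy):
        shell = contacts._sphere_points(30) * 2.2
        traj = make_toy(np.concatenate([[[0, 0, 0]], shell]))
        _, per_res = asa(traj, selection=np.array([0]))
        assert per_res["area"].iloc[0] == 0.0

    def test_two_sphere_analytic_cap(self, make_toy):
        """Two equal carbons at 3 Å: lost area per sphere is the 2πRh cap."""
        traj = make_toy([[0.0, 0, 0], [3.0, 0, 0]])
        total, _ = asa(traj, n_sphere_points=2000)
        r = 1.7 + 1.4
        h = r - 1.5  # cap height for equal spheres at d = 3
        expected = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * h)
        assert total == pytest.approx(expected, rel=0.01)

    def test_monotone_under_added_neighbors(self, make_toy):
        base = asa(make_toy([[0.0, 0, 0]]))[0]
        one = asa(make_toy([[0.0, 0, 0], [3.0, 0, 0]]), selection=np.array([0]))[0]
        two = asa(make_toy([[0.0, 0, 0], [3.0, 0, 0], [-3.0, 0, 0]]), selection=np.array([0]))[0]
        assert base > one > two

    def test_rigid_transform_invariance(self, make_toy):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(size=(12, 3)) * 3
        rot = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        a, _ = asa(make_toy(pts))
        b, _ = asa(make_toy(pts @ rot.T + [5, 6, 7]))
        # invariant up to quadrature error of the fixed sphere-point lattice
        assert a == pytest.approx(b, rel=5e-3)


def test_residue_contact_frequency_excludes_sequence_neighbors(make_toy):
    coords = np.zeros((2, 4, 3))
    coords[:, 1] = [2, 0, 0]
    coords[:, 2] = [4, 0, 0]
    coords[:, 3] = [6, 0, 0]
    traj = make_toy(coords, resids=[1, 2, 3, 4])
    t = contacts.residue_contact_frequency(traj, np.arange(4), atom_cutoff=2.5)
    pairs = set(zip(t.table["resid_a"], t.table["resid_b"]))
    assert pairs == set()  # all contacts are sequence neighbors
    t2 = contacts.residue_contact_frequency(
        traj, np.arange(4), atom_cutoff=2.5, exclude_sequence_neighbors=0
    )
    assert len(t2.table) == 3
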