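"""Descriptor correctness against independent oracles and rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from igg_allostery import geometry
from igg_allostery.errors import ConfigurationError, DegenerateGeometryError

rng = np.random.default_rng(2024)


class TestCom:
    def test_equal_mass_midpoint(self, make_toy):
        traj = make_toy([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(geometry.com(traj, [0, 1], frame=0), [1, 0, 0])

    def test_mass_weighting(self, make_toy):
        # carbon (12.011) at x=0, oxygen (15.999) at x=7
        traj = make_toy([[0, 0, 0], [7, 0, 0]], names=["C1", "O1"])
        expected = 15.999 * 7 / (12.011 + 15.999)
        assert geometry.com(traj, [0, 1], frame=0)[0] == pytest.approx(expected)

    def test_translation_equivariance(self, make_toy):
        pts = rng.normal(size=(6, 3))
        t = np.array([3.0, -2.0, 5.5])
        a = geometry.com(make_toy(pts), np.arange(6), frame=0)
        b = geometry.com(make_toy(pts + t), np.arange(6), frame=0)
        np.testing.assert_allclose(b - a, t, atol=1e-12)

    def test_empty_selection_raises(self, make_toy):
        with pytest.raises(ConfigurationError):
            geometry.com(make_toy(np.zeros((3, 3))), np.array([], dtype=int))


class TestDistance:
    def test_rigid_translation_invariance(self, make_toy):
        pts = rng.normal(size=(8, 3))
        frames = np.stack([pts + [i, 2 * i, 0] for i in range(5)])
        traj = make_toy(frames)
        d = geometry.com_distance_series(traj, np.arange(4), np.arange(4, 8))
        np.testing.assert_allclose(d.values, d.values[0], atol=1e-9)

    def test_self_distance_zero(self, make_toy):
        traj = make_toy(rng.normal(size=(2, 5, 3)))
        d = geometry.com_distance_series(traj, np.arange(5), np.arange(5))
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_symmetric(self, make_toy):
        traj = make_toy(rng.normal(size=(3, 6, 3)))
        a, b = np.arange(3), np.arange(3, 6)
        np.testing.assert_allclose(
            geometry.com_distance_series(traj, a, b).values,
            geometry.com_distance_series(traj, b, a).values,
        )


class TestAngles:
    def test_right_angle(self, make_toy):
        traj = make_toy([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert geometry.three_point_angle_series(traj, 0, 1, 2).values[0] == pytest.approx(90.0)

    def test_collinear_is_180(self, make_toy):
        traj = make_toy([[1, 0, 0], [0, 0, 0], [-2, 0, 0]])
        assert geometry.three_point_angle_series(traj, 0, 1, 2).values[0] == pytest.approx(180.0)

    def test_against_arccos_oracle(self, make_toy):
        pts = rng.normal(size=(100, 3, 3)) * 10
        traj = make_toy(pts)
        ours = geometry.three_point_angle_series(traj, 0, 1, 2).values
        for f in range(100):
            a = pts[f, 0] - pts[f, 1]
            b = pts[f, 2] - pts[f, 1]
            expected = np.degrees(
                np.arccos(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
            )
            assert ours[f] == pytest.approx(expected, abs=1e-9)

    def test_vertex_symmetry(self, make_toy):
        traj = make_toy(rng.normal(size=(10, 3, 3)))
        fwd = geometry.three_point_angle_series(traj, 0, 1, 2).values
        rev = geometry.three_point_angle_series(traj, 2, 1, 0).values
        np.testing.assert_allclose(fwd, rev, atol=1e-10)

    def test_coincident_points_raise(self, make_toy):
        traj = make_toy([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            geometry.three_point_angle_series(traj, 0, 1, 2)


class TestDihedral:
    def test_planar_cis_is_zero(self, make_toy):
        traj = make_toy([[1, -1, 0], [0, 0, 0], [0, 1, 0], [1, 2, 0]])
        assert geometry.dihedral_series(traj, 0, 1, 2, 3).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self, make_toy):
        traj = make_toy([[-1, -1, 0], [0, 0, 0], [0, 1, 0], [1, 2, 0]])
        assert geometry.dihedral_series(traj, 0, 1, 2, 3).values[0] == pytest.approx(180.0)

    def test_against_mdanalysis_oracle(self, make_toy):
        from MDAnalysis.lib.distances import calc_dihedrals

        pts = rng.normal(size=(50, 4, 3)) * 5
        traj = make_toy(pts)
        ours = geometry.dihedral_series(traj, 0, 1, 2, 3).values
        ref = np.degrees(calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3]))
        ref[np.isclose(ref, -180.0)] = 180.0
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_reversal_invariance_and_mirror_antisymmetry(self, make_toy):
        pts = rng.normal(size=(20, 4, 3))
        traj = make_toy(pts)
        fwd = geometry.dihedral_series(traj, 0, 1, 2, 3).values
        # reading the chain backwards leaves the torsion unchanged
        rev = geometry.dihedral_series(traj, 3, 2, 1, 0).values
        np.testing.assert_allclose(rev, fwd, atol=1e-9)
        # mirror reflection flips the sign (modulo the ±180° identification)
        mirrored = geometry.dihedral_series(make_toy(pts * [1, 1, -1]), 0, 1, 2, 3).values
        diff = np.abs((fwd + mirrored + 180.0) % 360.0 - 180.0)
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)


class TestPlaneNormal:
    @staticmethod
    def _ring(n=8, radius=4.0):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)], axis=1)

    def test_identical_planes_zero(self, make_toy):
        ring = self._ring()
        traj = make_toy(np.concatenate([ring, ring + [20, 0, 0]]))
        ang = geometry.plane_normal_angle_series(traj, np.arange(8), np.arange(8, 16))
        assert ang.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_planes(self, make_toy):
        xy = self._ring()
        xz = xy @ Rotation.from_euler("x", 90, degrees=True).as_matrix().T
        traj = make_toy(np.concatenate([xy, xz + [20, 0, 0]]))
        ang = geometry.plane_normal_angle_series(traj, np.arange(8), np.arange(8, 16))
        assert ang.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_constructed_rotation_angle(self, make_toy):
        xy = self._ring()
        rot = xy @ Rotation.from_euler("x", 30, degrees=True).as_matrix().T
        traj = make_toy(np.concatenate([xy, rot + [20, 0, 0]]))
        ang = geometry.plane_normal_angle_series(traj, np.arange(8), np.arange(8, 16))
        assert ang.values[0] == pytest.approx(30.0, abs=1e-6)

    def test_collinear_selection_raises(self, make_toy):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        traj = make_toy(np.concatenate([line, self._ring()]))
        with pytest.raises(DegenerateGeometryError):
            geometry.plane_normal_angle_series(traj, np.arange(5), np.arange(5, 13))


class TestGlycanState:
    def test_all_bound(self, make_toy):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 6.0
        _, bound = geometry.glycan_state_series(make_toy(frames), 1, 0)
        assert bound.all()

    def test_zero_cutoff_never_bound(self, make_toy):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 6.0
        _, bound = geometry.glycan_state_series(make_toy(frames), 1, 0, bound_cutoff=0.0)
        assert not bound.any()


class TestDensity2D:
    def test_point_mass_single_bin(self):
        h = geometry.density_2d(np.full(100, 70.0), np.full(100, 70.0))
        assert h.density.max() == pytest.approx(1.0)
        assert h.density.sum() == pytest.approx(1.0)

    def test_density_sums_to_one_any_binning(self):
        x, y = rng.uniform(50, 90, 1000), rng.uniform(50, 90, 1000)
        for bw in (1.0, 2.5, 7.0):
            assert geometry.density_2d(x, y, bw).density.sum() == pytest.approx(1.0)

    def test_two_planted_modes_recovered(self):
        """60/40 planted clusters are found with populations within 3 s.e."""
        n = 20000
        local = np.random.default_rng(17)
        lab = local.random(n) < 0.6
        x = np.where(lab, 65.0, 80.0) + 2.0 * local.standard_normal(n)
        y = np.where(lab, 80.0, 65.0) + 2.0 * local.standard_normal(n)
        modes = geometry.find_modes(geometry.density_2d(x, y))
        assert len(modes) == 2
        se = 3 * np.sqrt(0.6 * 0.4 / n)
        assert modes[0].population == pytest.approx(0.6, abs=max(se, 0.01))
        assert modes[1].population == pytest.approx(0.4, abs=max(se, 0.01))
        assert (modes[0].x, modes[0].y) == pytest.approx((65, 80), abs=2.5)

    def test_uniform_anticoncentration(self):
        local = np.random.default_rng(3)
        x, y = local.uniform(0, 100, 100000), local.uniform(0, 100, 100000)
        h = geometry.density_2d(x, y, 5.0)
        occupied = h.density[h.density > 0]
        assert h.density.max() <= 3 * occupied.mean()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            geometry.density_2d(np.array([]), np.array([]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_descriptors_invariant_under_rigid_transform(seed):
    """Distances/angles/dihedrals are unchanged by any global rotation+translation."""
    from conftest import toy_trajectory

    local = np.random.default_rng(seed)
    pts = local.normal(size=(3, 9, 3)) * 8
    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    t = local.uniform(-100, 100, 3)
    moved = pts @ rot.T + t
    a, b = toy_trajectory(pts), toy_trajectory(moved)
    np.testing.assert_allclose(
        geometry.com_distance_series(a, np.arange(4), np.arange(4, 9)).values,
        geometry.com_distance_series(b, np.arange(4), np.arange(4, 9)).values,
        atol=1e-6,
    )
    np.testing.assert_allclose(
        geometry.three_point_angle_series(a, 0, 1, 2).values,
        geometry.three_point_angle_series(b, 0, 1, 2).values,
        atol=1e-6,
    )
    np.testing.assert_allclose(
        geometry.dihedral_series(a, 0, 1, 2, 3).values,
        geometry.dihedral_series(b, 0, 1, 2, 3).values,
        atol=1e-6,
    )
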