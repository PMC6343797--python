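"""DCCM and order-parameter estimators: limits, oracles, planted recovery."""

import numpy as np
import pytest

from igg_allostery import dynamics, synthetic
from igg_allostery.dynamics import (
    dccm,
    order_parameters,
    region_mean_change,
    s2_from_vectors,
)

rng = np.random.default_rng(512)


def brute_force_dccm(x: np.ndarray) -> np.ndarray:
    """Direct-summation oracle over (F, N, 3) coordinates."""
    f, n, _ = x.shape
    dx = x - x.mean(axis=0)
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(np.dot(dx[t, i], dx[t, j]) for t in range(f)) / f
            di = sum(np.dot(dx[t, i], dx[t, i]) for t in range(f)) / f
            dj = sum(np.dot(dx[t, j], dx[t, j]) for t in range(f)) / f
            c[i, j] = num / np.sqrt(di * dj)
    return c


def brute_force_s2(u: np.ndarray) -> float:
    """Second-moment-matrix oracle: S² = (3 Tr(Q²) − 1)/2 with Q = ⟨u uᵀ⟩."""
    q = np.einsum("fi,fj->ij", u, u) / len(u)
    return float((3.0 * np.trace(q @ q) - 1.0) / 2.0)


class TestDccm:
    def test_self_correlation_unity(self, make_toy):
        traj = make_toy(rng.normal(size=(50, 3, 3)))
        cm = dccm(traj, np.arange(3))
        np.testing.assert_allclose(np.diag(cm.values), 1.0)

    def test_shared_displacement_perfectly_correlated(self, make_toy):
        z = rng.normal(size=100)
        coords = np.zeros((100, 2, 3))
        coords[:, 0, 2] = z
        coords[:, 1, 2] = z
        cm = dccm(make_toy(coords), np.array([0, 1]))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_antiphase_anticorrelated(self, make_toy):
        z = rng.normal(size=100)
        coords = np.zeros((100, 2, 3))
        coords[:, 0, 2] = z
        coords[:, 1, 2] = -z
        cm = dccm(make_toy(coords), np.array([0, 1]))
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, make_toy):
        coords = rng.normal(size=(100, 10, 3))
        traj = make_toy(coords)
        cm = dccm(traj, np.arange(10))
        np.testing.assert_allclose(cm.values, brute_force_dccm(coords), atol=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, small_antibody):
        traj, dmap, _ = small_antibody
        nodes = np.array([
            i for i in range(traj.topology.n_atoms)
            if str(traj.topology.atom_names[i]) == "CA"
        ])
        cm = dccm(traj, nodes)
        np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert np.abs(cm.values).max() <= 1.0 + 1e-12

    def test_zero_variance_node_zeroed(self, make_toy):
        coords = rng.normal(size=(30, 2, 3))
        coords[:, 1, :] = 5.0  # static atom
        cm = dccm(make_toy(coords), np.array([0, 1]))
        assert cm.values[0, 1] == 0.0
        assert cm.values[1, 1] == 1.0

    @pytest.mark.parametrize("rho", [-0.8, 0.0, 0.5])
    def test_planted_correlation_recovered(self, rho):
        """Latent-factor planted ρ recovers within 3 s.e. (Fisher-z scale)."""
        n = 10000
        spec = synthetic.SyntheticSpec(
            n_frames=n, seed=31 + int(10 * abs(rho)),
            cluster_spec=[synthetic.ClusterComponent(1.0, 70, 70, 0.0)],
            correlation_spec=[synthetic.CorrelationTarget("fab1", "fab2", rho)],
            order_spec={},
        )
        traj, dmap, _ = synthetic.generate_antibody_trajectory(spec)
        ca1 = [i for i in dmap.select("fab1") if traj.topology.atom_names[i] == "CA"][0]
        ca2 = [i for i in dmap.select("fab2") if traj.topology.atom_names[i] == "CA"][0]
        cm = dccm(traj, np.array([ca1, ca2]))
        se = (1 - rho**2) / np.sqrt(n)
        assert cm.values[0, 1] == pytest.approx(rho, abs=3 * max(se, 1e-3))


class TestOrderParameters:
    def test_static_vector_unity(self):
        u = np.tile([0.0, 0.0, 1.0], (100, 1, 1))
        np.testing.assert_allclose(s2_from_vectors(u), 1.0)

    def test_alternating_x_z_quarter(self):
        """Equal occupancy of +x and +z gives S² = 0.25 by direct evaluation."""
        u = np.zeros((100, 1, 3))
        u[::2, 0, 0] = 1.0
        u[1::2, 0, 2] = 1.0
        assert s2_from_vectors(u)[0] == pytest.approx(0.25)

    def test_isotropic_limit_near_zero(self):
        local = np.random.default_rng(8)
        v = local.normal(size=(100000, 1, 3))
        u = v / np.linalg.norm(v, axis=2, keepdims=True)
        assert s2_from_vectors(u)[0] < 0.02

    def test_matches_second_moment_oracle(self):
        v = rng.normal(size=(200, 1, 3)) + [0, 0, 2.0]
        u = v / np.linalg.norm(v, axis=2, keepdims=True)
        assert s2_from_vectors(u)[0] == pytest.approx(brute_force_s2(u[:, 0, :]), abs=1e-12)

    def test_sign_flip_and_time_reversal_invariance(self):
        v = rng.normal(size=(300, 4, 3))
        u = v / np.linalg.norm(v, axis=2, keepdims=True)
        base = s2_from_vectors(u)
        np.testing.assert_allclose(s2_from_vectors(-u), base, atol=1e-12)
        np.testing.assert_allclose(s2_from_vectors(u[::-1]), base, atol=1e-12)

    @pytest.mark.parametrize("target", [0.25, 0.85, 1.0])
    def test_planted_cone_s2_recovered(self, target):
        spec = synthetic.SyntheticSpec(
            n_frames=5000, seed=int(100 * target),
            cluster_spec=[synthetic.ClusterComponent(1.0, 70, 70, 0.0)],
            order_spec={"fab1": target},
        )
        traj, dmap, _ = synthetic.generate_antibody_trajectory(spec)
        pairs = dynamics.backbone_co_pairs(traj, dmap.select("fab1"))
        prof = order_parameters(traj, pairs)
        tol = 1e-12 if target == 1.0 else 0.04
        np.testing.assert_allclose(prof.s2, target, atol=tol)


class TestRegionMeanChange:
    def _profile(self, ids, vals):
        return dynamics.OrderParameterProfile(np.array(ids), np.array(vals))

    def test_identical_profiles_zero(self):
        p = self._profile([1, 2, 3], [0.5, 0.6, 0.7])
        assert region_mean_change(p, p, {1, 2, 3}) == 0.0

    def test_scaled_profile(self):
        a = self._profile([1, 2], [0.4, 0.6])
        b = self._profile([1, 2], [0.6, 0.9])
        assert region_mean_change(a, b, {1, 2}) == pytest.approx(0.5)

    def test_planted_hinge_rigidification(self):
        """Hinge S² planted 0.4 → 0.48 reads out as a ≈ +20 % change."""
        profiles = []
        for seed, s2 in ((1, 0.4), (2, 0.48)):
            spec = synthetic.SyntheticSpec(
                n_frames=4000, seed=seed,
                cluster_spec=[synthetic.ClusterComponent(1.0, 70, 70, 0.0)],
                order_spec={"hinge": s2},
            )
            traj, dmap, _ = synthetic.generate_antibody_trajectory(spec)
            pairs = dynamics.backbone_co_pairs(traj, dmap.select("hinge"))
            profiles.append((order_parameters(traj, pairs),
                             {int(traj.topology.residue_ids[i]) for i in dmap.select("hinge")}))
        (pa, region), (pb, _) = profiles
        assert region_mean_change(pa, pb, region) == pytest.approx(0.20, abs=0.05)

    def test_empty_overlap_raises(self):
        from igg_allostery.errors import ConfigurationError

        a = self._profile([1], [0.5])
        b = self._profile([2], [0.5])
        with pytest.raises(ConfigurationError):
            region_mean_change(a, b, {3})
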