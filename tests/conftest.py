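"""Shared fixtures: small synthetic trajectories and structures."""

import numpy as np
import pytest

from igg_allostery import synthetic
from igg_allostery.core_io import Topology, Trajectory


@pytest.fixture(scope="session")
def small_antibody():
    """A 200-frame antibody trajectory with default planted structure."""
    spec = synthetic.SyntheticSpec(n_frames=200, seed=42)
    return synthetic.generate_antibody_trajectory(spec)


@pytest.fixture(scope="session")
def quiet_antibody():
    """A geometry-quiescent antibody: single cluster, zero jitter, static bonds."""
    spec = synthetic.SyntheticSpec(
        n_frames=50,
        seed=7,
        cluster_spec=[synthetic.ClusterComponent(1.0, 70.0, 70.0, 0.0)],
        order_spec={},
        glycan_spec={},
    )
    return synthetic.generate_antibody_trajectory(spec)


@pytest.fixture(scope="session")
def y_structure():
    """Single-frame Y-shaped structure with hinge torsion anchors."""
    return synthetic.make_y_structure()


def toy_trajectory(coords, names=None, resids=None, resnames=None, chains=None):
    """Build a minimal trajectory from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    top = Topology.from_atoms(
        atom_names=names or [f"C{i + 1}" for i in range(n)],
        residue_ids=resids if resids is not None else np.arange(1, n + 1),
        residue_names=resnames or ["ALA"] * n,
        chain_ids=chains or ["A"] * n,
    )
    return Trajectory(top, coords)


@pytest.fixture
def make_toy():
    return toy_trajectory
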