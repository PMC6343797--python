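"""Dynamic cross-correlation and backbone order parameters.

Two residue-level dynamics statistics:

* the dynamic cross-correlation matrix (DCCM), the normalized covariance
  of positional fluctuations, C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩),
  in [−1, 1], with Δr the deviation from the atom's trajectory-mean
  position — values near ±1 mean two residues move in the same/opposite
  direction in most frames;
* the generalized (model-free, second-rank) order parameter S² of
  backbone C=O bond vectors, 1 for a rigidly oriented bond and 0 in the
  isotropic limit, computed from the second moments of the unit bond
  vector:  S² = (3(⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1)/2.

Both statistics assume global rigid-body motion has been removed; by
default the trajectory is superposed on a caller-chosen selection first.
Correlations are equal-time only (no time lags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from igg_allostery.clustering import superpose
from igg_allostery.core_io import Trajectory
from igg_allostery.errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Residue-level DCCM: symmetric, unit diagonal, values in [−1, 1]."""

    node_labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.node_labels)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch with labels")

    def lookup(self, label_i, label_j) -> float:
        i = self.node_labels.index(label_i)
        j = self.node_labels.index(label_j)
        return float(self.values[i, j])


@dataclass
class OrderParameterProfile:
    """Per-residue S² values in [0, 1]."""

    residue_ids: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.s2 = np.asarray(self.s2, dtype=np.float64)
        if len(self.residue_ids) != len(self.s2):
            raise ValueError("residue ids / s2 length mismatch")


def dccm(
    traj: Trajectory,
    node_atoms: np.ndarray,
    node_labels: list | None = None,
    superpose_selection: np.ndarray | None = None,
    ref_frame: int = 0,
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over one node atom per residue.

    Parameters
    ----------
    node_atoms : atom index per network node (conventionally the Cα of
        each residue; ring C1 for glycan nodes).
    superpose_selection : when given, the trajectory is least-squares
        fitted on this selection first to strip global motion.

    A zero-variance node yields a zero row/column with unit diagonal and
    a logged warning rather than NaNs.
    """
    nodes = np.asarray(node_atoms, dtype=np.int64)
    if len(nodes) == 0:
        raise ConfigurationError("dccm needs at least one node atom")
    if superpose_selection is not None:
        traj = superpose(traj, superpose_selection, ref_frame)
    x = traj.coordinates[:, nodes, :]
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fik,fjk->ij", dx, dx) / traj.n_frames
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    if np.any(zero):
        logger.warning("%d zero-variance DCCM node(s); rows zeroed", int(zero.sum()))
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    c = cov / norm
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    if node_labels is None:
        node_labels = [int(traj.topology.residue_ids[i]) for i in nodes]
    return CorrelationMatrix(node_labels=list(node_labels), values=c)


def bond_vectors(traj: Trajectory, c_atoms: np.ndarray, o_atoms: np.ndarray) -> np.ndarray:
    """Unit C→O bond vectors, shape (F, n_bonds, 3)."""
    v = traj.coordinates[:, np.asarray(o_atoms), :] - traj.coordinates[:, np.asarray(c_atoms), :]
    n = np.linalg.norm(v, axis=2, keepdims=True)
    if np.any(n < 1e-12):
        raise ConfigurationError("zero-length bond vector")
    return v / n


def s2_from_vectors(u: np.ndarray) -> np.ndarray:
    """Generalized order parameter of unit-vector series, shape (F, n, 3) → (n,)."""
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    s2 = 0.5 * (
        3.0
        * (
            (x * x).mean(axis=0) ** 2
            + (y * y).mean(axis=0) ** 2
            + (z * z).mean(axis=0) ** 2
            + 2.0 * (x * y).mean(axis=0) ** 2
            + 2.0 * (x * z).mean(axis=0) ** 2
            + 2.0 * (y * z).mean(axis=0) ** 2
        )
        - 1.0
    )
    return np.clip(s2, 0.0, 1.0)


def order_parameters(
    traj: Trajectory,
    bond_pairs: list[tuple[int, int, int]],
    superpose_selection: np.ndarray | None = None,
    ref_frame: int = 0,
) -> OrderParameterProfile:
    """S² of per-residue C=O bond vectors.

    ``bond_pairs`` is a list of (C atom index, O atom index, residue id).
    Residues whose O atom is missing are simply not in the list (the
    caller builds pairs from the topology; see
    :func:`backbone_co_pairs`).
    """
    if not bond_pairs:
        raise ConfigurationError("no C=O bond pairs")
    if superpose_selection is not None:
        traj = superpose(traj, superpose_selection, ref_frame)
    c_idx = np.array([p[0] for p in bond_pairs])
    o_idx = np.array([p[1] for p in bond_pairs])
    resids = np.array([p[2] for p in bond_pairs])
    u = bond_vectors(traj, c_idx, o_idx)
    return OrderParameterProfile(residue_ids=resids, s2=s2_from_vectors(u))


def backbone_co_pairs(traj: Trajectory, selection: np.ndarray | None = None):
    """Find (C, O, residue id) backbone carbonyl pairs in a topology.

    Residues lacking either atom (C-terminal variants) are skipped with
    a log message.
    """
    top = traj.topology
    atoms = np.asarray(selection) if selection is not None else np.arange(top.n_atoms)
    res_idx, res_keys = top.residue_index()
    by_res: dict[int, dict[str, int]] = {}
    for i in atoms:
        name = str(top.atom_names[i]).strip()
        if name in ("C", "O"):
            by_res.setdefault(res_idx[i], {})[name] = int(i)
    pairs = []
    for ri in sorted(by_res):
        d = by_res[ri]
        if "C" in d and "O" in d:
            pairs.append((d["C"], d["O"], int(res_keys[ri][1])))
        else:
            logger.info("residue %s lacks C or O atom; skipped for S2", res_keys[ri])
    return pairs


def region_mean_change(
    profile_a: OrderParameterProfile,
    profile_b: OrderParameterProfile,
    region: set[int] | np.ndarray,
) -> float:
    """Fractional change of the region-mean S² from profile A to B.

    ``(mean_b − mean_a) / mean_a`` over residues of ``region`` present
    in both profiles — e.g. +0.2 for a 20 % hinge rigidification.
    """
    region = set(int(r) for r in region)
    ids_a = {int(r): i for i, r in enumerate(profile_a.residue_ids)}
    ids_b = {int(r): i for i, r in enumerate(profile_b.residue_ids)}
    common = sorted(region & set(ids_a) & set(ids_b))
    if not common:
        raise ConfigurationError("region has no residues common to both profiles")
    mean_a = float(np.mean([profile_a.s2[ids_a[r]] for r in common]))
    mean_b = float(np.mean([profile_b.s2[ids_b[r]] for r in common]))
    if mean_a == 0:
        raise ZeroDivisionError("region mean S2 of reference profile is zero")
    return (mean_b - mean_a) / mean_a
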