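"""Superposition, RMSD and quality-threshold conformational clustering.

The workflow mirrors the standard trajectory-population analysis:
superpose every frame on a reference sub-domain (e.g. CH3), compute
pairwise RMSD over an analysis selection (e.g. the whole Fc), then run
greedy quality-threshold (QT) clustering — repeatedly extract the frame
with the most neighbors within an RMSD cutoff together with those
neighbors — and report per-cluster population fractions.  Cross-ensemble
mean-RMSD matrices compare conformational ensembles of several systems.

RMSD here is unweighted (coordinate RMSD over the selection); centers
of mass elsewhere in the package are mass-weighted.  This asymmetry
follows common trajectory-tool defaults and is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from igg_allostery.core_io import Trajectory
from igg_allostery.errors import ConfigurationError, DegenerateGeometryError


@dataclass
class ClusterAssignment:
    """QT clustering result: labels (−1 = unassigned), centroid frames, populations."""

    labels: np.ndarray
    centroids: list[int]
    populations: np.ndarray
    cutoff: float
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def kabsch_rotation(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation matrix mapping centered ``mobile`` onto
    centered ``ref`` (no reflection)."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return (u @ diag @ vt).T


def superpose(traj: Trajectory, ref_selection: np.ndarray, ref_frame: int = 0) -> Trajectory:
    """Rigidly fit every frame onto ``ref_frame`` using ``ref_selection``.

    Each frame is rotated/translated to minimize the selection RMSD to
    its coordinates in the reference frame; the transform is applied to
    all atoms.  The rotation is the optimal proper rotation (Kabsch via
    SVD, reflections excluded).
    """
    sel = np.asarray(ref_selection, dtype=np.int64)
    if len(sel) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 reference atoms")
    ref = traj.coordinates[ref_frame, sel, :]
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("reference selection is collinear")
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        mob = traj.coordinates[f, sel, :]
        center = mob.mean(axis=0)
        rot = kabsch_rotation(mob - center, ref_c)
        out[f] = (traj.coordinates[f] - center) @ rot.T + ref_center
    return traj.with_coordinates(out)


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Root-mean-square deviation (Å) between two frames over a selection.

    No fitting is performed; superpose first if a fitted RMSD is wanted.
    """
    if selection is not None:
        selection = np.asarray(selection, dtype=np.int64)
        if len(selection) == 0:
            raise ConfigurationError("RMSD of empty selection")
        frame_a = frame_a[selection]
        frame_b = frame_b[selection]
    if frame_a.shape != frame_b.shape:
        raise ConfigurationError("frames have different selection shapes")
    if frame_a.shape[0] == 0:
        raise ConfigurationError("RMSD of empty selection")
    return float(np.sqrt(np.mean(np.sum((frame_a - frame_b) ** 2, axis=1))))


def pairwise_rmsd_matrix(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """All-pairs unfitted RMSD matrix over a selection, via the Gram trick.

    ``rmsd²(i,j) = (|x_i|² + |x_j|² − 2 x_i·x_j) / A`` with frames
    flattened to 3A-vectors — one BLAS matmul instead of F² loops.
    """
    sel = np.asarray(selection, dtype=np.int64)
    if len(sel) == 0:
        raise ConfigurationError("empty selection")
    x = traj.coordinates[:, sel, :].reshape(traj.n_frames, -1)
    sq = np.einsum("ij,ij->i", x, x)
    g = x @ x.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * g) / len(sel)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


def qt_cluster(
    traj: Trajectory,
    selection: np.ndarray,
    cutoff: float = 4.0,
    max_clusters: int = 5,
) -> ClusterAssignment:
    """Greedy quality-threshold clustering of a (pre-superposed) trajectory.

    Repeatedly find the frame with the most unassigned neighbors within
    ``cutoff`` Å RMSD, emit it as a centroid with its neighbors as one
    cluster, and remove them; stop after ``max_clusters`` clusters.  The
    remainder stays unassigned (label −1).  Ties in neighbor count go to
    the lowest frame index, so the result is deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    dmat = pairwise_rmsd_matrix(traj, selection)
    n = traj.n_frames
    labels = np.full(n, -1, dtype=np.int64)
    unassigned = np.ones(n, dtype=bool)
    centroids: list[int] = []
    populations: list[float] = []
    within = dmat <= cutoff
    for c in range(max_clusters):
        if not unassigned.any():
            break
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & unassigned)
        labels[members] = c
        unassigned[members] = False
        centroids.append(center)
        populations.append(len(members) / n)
    return ClusterAssignment(
        labels=labels,
        centroids=centroids,
        populations=np.asarray(populations),
        cutoff=cutoff,
        meta={"max_clusters": max_clusters, "n_frames": n},
    )


def cross_ensemble_mean_rmsd(
    ensembles: list[Trajectory],
    selection: np.ndarray,
    stride: int = 1,
) -> tuple[np.ndarray, dict]:
    """Mean pairwise RMSD between (and within) conformational ensembles.

    Entry (i, j) is the mean unfitted RMSD over all frame pairs between
    ensemble i and ensemble j (diagonal: distinct pairs only).  All
    ensembles must share the selection's atom count and a common
    reference superposition.  ``stride`` subsamples frames; it is
    recorded in the returned metadata.
    """
    sel = np.asarray(selection, dtype=np.int64)
    xs = []
    for e in ensembles:
        if sel.max(initial=-1) >= e.n_atoms:
            raise ConfigurationError("selection exceeds ensemble atom count")
        xs.append(e.coordinates[::stride, sel, :].reshape(-1, len(sel) * 3))
    if len({x.shape[1] for x in xs}) != 1:
        raise ConfigurationError("ensembles have incompatible selection sizes")
    k = len(xs)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            a, b = xs[i], xs[j]
            sqa = np.einsum("ij,ij->i", a, a)
            sqb = np.einsum("ij,ij->i", b, b)
            d2 = (sqa[:, None] + sqb[None, :] - 2.0 * (a @ b.T)) / len(sel)
            d = np.sqrt(np.clip(d2, 0.0, None))
            if i == j:
                n = d.shape[0]
                mean = d[np.triu_indices(n, k=1)].mean() if n > 1 else 0.0
            else:
                mean = d.mean()
            out[i, j] = out[j, i] = mean
    return out, {"stride": stride, "n_frames": [x.shape[0] for x in xs]}
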