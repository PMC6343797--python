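"""Interface contact frequencies, accumulated contact maps and ASA.

A residue pair (one residue from each group) is "in contact" in a frame
iff any heavy-atom pair across the groups lies within a distance cutoff
(default 3 Å for interface tables; 4.5 Å is the dynamical-network
convention).  Summing over frames gives the accumulated contact map;
dividing by the frame count gives contact frequencies, from which key
binding residues are defined by a strict frequency threshold (> 20 %
in the standard analysis).

Solvent-accessible surface area uses the Shrake–Rupley rolling-probe
quadrature: each atom's sphere of radius (r_vdw + probe) is sampled at
``n_sphere_points`` near-uniform points (golden-spiral lattice) and the
unoccluded fraction scaled to the sphere area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from igg_allostery.core_io import Topology, Trajectory
from igg_allostery.errors import ConfigurationError


@dataclass
class ContactFrequencyTable:
    """Canonical residue-pair contact frequencies over a frame range.

    ``table`` columns: resid_a, resname_a, resid_b, resname_b, frequency
    (fraction in [0, 1]); each pair appears once, group-A residue first.
    """

    table: pd.DataFrame
    cutoff: float
    frame_range: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def _group_residues(top: Topology, group: np.ndarray, heavy_only: bool):
    """Per-group atom indices plus their residue factorization."""
    group = np.asarray(group, dtype=np.int64)
    if heavy_only:
        group = group[top.heavy_mask()[group]]
    res_idx, res_keys = top.residue_index()
    sub = res_idx[group]
    uniq, local = np.unique(sub, return_inverse=True)
    labels = [res_keys[u] for u in uniq]
    resids = [int(top.residue_ids[np.flatnonzero(res_idx == u)[0]]) for u in uniq]
    resnames = [str(top.residue_names[np.flatnonzero(res_idx == u)[0]]) for u in uniq]
    return group, local, resids, resnames


def accumulated_contact_map(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    atom_cutoff: float = 3.0,
    frame_range: tuple[int, int] | None = None,
    heavy_only: bool = True,
):
    """Residue×residue matrix counting frames with any cross-group contact.

    Returns ``(counts, resids_a, resnames_a, resids_b, resnames_b, n_frames)``.
    Groups must be disjoint (intermolecular semantics).
    """
    if np.intersect1d(group_a, group_b).size:
        raise ConfigurationError("groups overlap; contact groups must be disjoint")
    top = traj.topology
    atoms_a, res_a, resids_a, resnames_a = _group_residues(top, group_a, heavy_only)
    atoms_b, res_b, resids_b, resnames_b = _group_residues(top, group_b, heavy_only)
    if len(atoms_a) == 0 or len(atoms_b) == 0:
        raise ConfigurationError("contact group empty after hydrogen filtering")
    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    counts = np.zeros((len(resids_a), len(resids_b)), dtype=np.int64)
    for f in range(lo, hi):
        xa = traj.coordinates[f, atoms_a, :]
        xb = traj.coordinates[f, atoms_b, :]
        pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=atom_cutoff)
        seen: set[tuple[int, int]] = set()
        for ia, hits in enumerate(pairs):
            for ib in hits:
                seen.add((res_a[ia], res_b[ib]))
        for ra, rb in seen:
            counts[ra, rb] += 1
    return counts, resids_a, resnames_a, resids_b, resnames_b, hi - lo


def contact_frequency(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    atom_cutoff: float = 3.0,
    frame_range: tuple[int, int] | None = None,
    heavy_only: bool = True,
) -> ContactFrequencyTable:
    """Contact-frequency table between two disjoint atom groups.

    Frequency = (frames with any heavy-atom pair within ``atom_cutoff``)
    / (frames analysed).  Hydrogens are excluded by default since the
    interface criterion is a heavy-atom one; pass ``heavy_only=False``
    for the literal all-atom reading.
    """
    counts, resids_a, resnames_a, resids_b, resnames_b, n = accumulated_contact_map(
        traj, group_a, group_b, atom_cutoff, frame_range, heavy_only
    )
    ia, ib = np.nonzero(counts)
    rows = {
        "resid_a": [resids_a[i] for i in ia],
        "resname_a": [resnames_a[i] for i in ia],
        "resid_b": [resids_b[i] for i in ib],
        "resname_b": [resnames_b[i] for i in ib],
        "frequency": [counts[i, j] / n for i, j in zip(ia, ib)],
    }
    df = pd.DataFrame(rows).sort_values(
        ["frequency", "resid_a", "resid_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    return ContactFrequencyTable(table=df, cutoff=atom_cutoff, frame_range=(lo, hi))


def residue_contact_frequency(
    traj: Trajectory,
    selection: np.ndarray,
    atom_cutoff: float = 4.5,
    exclude_sequence_neighbors: int = 1,
    frame_range: tuple[int, int] | None = None,
) -> ContactFrequencyTable:
    """Intra-selection residue-pair contact frequencies (network edges).

    Used to build dynamical-network edges: heavy-atom residue contacts
    within ``atom_cutoff`` (default 4.5 Å), excluding pairs closer than
    ``exclude_sequence_neighbors`` in residue number on the same chain
    (trivially bonded neighbors).
    """
    top = traj.topology
    atoms, res_local, resids, resnames = _group_residues(top, selection, heavy_only=True)
    chains: list[str] = []
    res_idx, res_keys = top.residue_index()
    for rid in resids:
        pos = np.flatnonzero(top.residue_ids == rid)[0]
        chains.append(str(top.chain_ids[pos]))
    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    nres = len(resids)
    counts = np.zeros((nres, nres), dtype=np.int64)
    for f in range(lo, hi):
        x = traj.coordinates[f, atoms, :]
        tree = cKDTree(x)
        seen: set[tuple[int, int]] = set()
        for i, j in tree.query_pairs(r=atom_cutoff):
            ri, rj = res_local[i], res_local[j]
            if ri != rj:
                seen.add((min(ri, rj), max(ri, rj)))
        for ri, rj in seen:
            counts[ri, rj] += 1
    rows = []
    for ri in range(nres):
        for rj in range(ri + 1, nres):
            if counts[ri, rj] == 0:
                continue
            if (
                chains[ri] == chains[rj]
                and abs(resids[ri] - resids[rj]) <= exclude_sequence_neighbors
            ):
                continue
            rows.append(
                (resids[ri], resnames[ri], resids[rj], resnames[rj], counts[ri, rj] / (hi - lo))
            )
    df = pd.DataFrame(
        rows, columns=["resid_a", "resname_a", "resid_b", "resname_b", "frequency"]
    )
    return ContactFrequencyTable(table=df, cutoff=atom_cutoff, frame_range=(lo, hi))


def key_binding_residues(table: ContactFrequencyTable, threshold: float = 0.2) -> set[int]:
    """Residues in any pair with contact frequency strictly above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    df = table.table
    hot = df[df["frequency"] > threshold]
    return set(hot["resid_a"]).union(hot["resid_b"])


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points via the golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def asa(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    frame: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Shrake–Rupley solvent-accessible surface area of a selection (Å²).

    Every atom of the topology occludes; area is reported for the
    selection's atoms only, as (total, per-residue table).  Quadrature
    error at the default 960 points is below 1 % for typical radii.
    """
    top = traj.topology
    coords = traj.coordinates[frame]
    radii = top.radii + probe_radius
    sel = np.asarray(selection, dtype=np.int64) if selection is not None else np.arange(top.n_atoms)
    if sel.size == 0:
        raise ConfigurationError("ASA of empty selection")
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(len(sel))
    for k, i in enumerate(sel):
        ri = radii[i]
        pts = coords[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
            if not accessible.any():
                break
        per_atom[k] = 4.0 * np.pi * ri * ri * accessible.sum() / n_sphere_points
    res_idx, res_keys = top.residue_index()
    df = pd.DataFrame(
        {
            "chain": [res_keys[res_idx[i]][0] for i in sel],
            "resid": [res_keys[res_idx[i]][1] for i in sel],
            "area": per_atom,
        }
    )
    per_res = df.groupby(["chain", "resid"], sort=True)["area"].sum().reset_index()
    return float(per_atom.sum()), per_res
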