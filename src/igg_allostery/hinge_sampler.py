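"""Hinge-torsion conformer enumeration, clash filtering and selection.

Starting conformations for antibody simulations are generated by
sweeping three successive hinge backbone torsions on a fixed grid
(default 60° steps → 6³ = 216 conformers) with the Fc held fixed and
the Fab arms riding on the rotations.  Conformers with atomic clashes
between domains or with a closed Fab pair are discarded, and a
descriptor-space spread (farthest-point sampling over (D_ab, D_ac)) of
the survivors picks the requested number of starting structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from igg_allostery.core_io import Trajectory
from igg_allostery.errors import SpecError


@dataclass
class TorsionSweepSpec:
    """Three torsion quadruples, their mobile atom sets, and sweep parameters.

    ``mobile_selections[k]`` lists the atoms rotated about torsion k's
    p2→p3 axis; it must contain p4 of torsion k (and everything distal)
    and no atoms of ``fixed_selection``.  Successive mobile sets should
    be nested (each later set a subset of the earlier) so that setting
    one torsion does not disturb the previous ones.
    """

    torsions: list[tuple[int, int, int, int]]
    mobile_selections: list[np.ndarray]
    fixed_selection: np.ndarray
    step: float = 60.0
    clash_cutoff: float = 2.0
    closed_fab_floor: float = 40.0

    def validate(self) -> None:
        if len(self.torsions) != len(self.mobile_selections):
            raise SpecError("one mobile selection per torsion required")
        if abs(360.0 / self.step - round(360.0 / self.step)) > 1e-9:
            raise SpecError("360 must be divisible by step")
        fixed = set(np.asarray(self.fixed_selection).tolist())
        for quad, mob in zip(self.torsions, self.mobile_selections):
            if len(quad) != 4:
                raise SpecError("torsion anchors must be quadruples")
            overlap = fixed & set(np.asarray(mob).tolist())
            if overlap:
                raise SpecError(f"atoms {sorted(overlap)[:5]} in both fixed and mobile sets")
            if int(quad[3]) not in set(np.asarray(mob).tolist()):
                raise SpecError("mobile selection must contain the torsion's p4 atom")


@dataclass
class ConformerSet:
    """Enumerated conformers: (n, A, 3) coordinates plus their grid angles."""

    topology: object
    coordinates: np.ndarray
    grid_angles: np.ndarray  # (n, 3) target torsions in degrees
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.coordinates.shape[0]


def _measure_torsion(coords: np.ndarray, quad) -> float:
    """Current dihedral (degrees) of one anchor quadruple in a single frame."""
    p1, p2, p3, p4 = (coords[int(i)] for i in quad)
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2u)
    ang = np.degrees(np.arctan2(-np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def enumerate_conformations(structure: Trajectory, spec: TorsionSweepSpec) -> ConformerSet:
    """Enumerate one conformer per torsion triple on the (360/step)³ grid.

    For each grid triple the torsions are set in order (1, then 2, then
    3) by rotating that torsion's mobile atoms about its p2→p3 axis by
    the difference between the target and the currently measured value.
    Rotation order matters because hinge torsions do not commute; with
    nested mobile sets each conformer measures back exactly its grid
    triple.  Fc (fixed-selection) coordinates are bit-identical across
    conformers.
    """
    spec.validate()
    base = structure.coordinates[0]
    n_steps = int(round(360.0 / spec.step))
    angles = np.arange(n_steps) * spec.step
    angles = np.where(angles > 180.0, angles - 360.0, angles)  # dihedral convention
    grid = np.array([(a, b, c) for a in angles for b in angles for c in angles])
    out = np.empty((len(grid), base.shape[0], 3))
    mobiles = [np.asarray(m, dtype=np.int64) for m in spec.mobile_selections]
    for g, triple in enumerate(grid):
        coords = base.copy()
        for k, target in enumerate(triple):
            quad = spec.torsions[k]
            current = _measure_torsion(coords, quad)
            delta = np.radians(target - current)
            p2, p3 = coords[int(quad[1])], coords[int(quad[2])]
            axis = p3 - p2
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(delta * axis)
            coords[mobiles[k]] = rot.apply(coords[mobiles[k]] - p3) + p3
        out[g] = coords
    return ConformerSet(
        topology=structure.topology,
        coordinates=out,
        grid_angles=grid,
        meta={"step": spec.step, "n_steps": n_steps},
    )


def clash_filter(
    conformers: ConformerSet,
    domain_selections: dict[str, np.ndarray],
    cutoff: float = 2.0,
    closed_fab_floor: float = 40.0,
    heavy_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Reject conformers with inter-domain clashes or a closed Fab pair.

    A conformer is rejected iff any heavy-atom pair across the checked
    domain pairs (fab1–fab2, fab1–fc, fab2–fc) lies closer than
    ``cutoff`` Å, or its Fab–Fab COM distance falls below
    ``closed_fab_floor``.  Returns (retained indices, report) where the
    report lists each conformer's minimum inter-domain distance, D_ab
    and verdict.
    """
    if cutoff <= 0:
        raise SpecError("clash cutoff must be positive")
    pairs = [("fab1", "fab2"), ("fab1", "fc"), ("fab2", "fc")]
    sels = {}
    for name in ("fab1", "fab2", "fc"):
        s = np.asarray(domain_selections[name], dtype=np.int64)
        if heavy_mask is not None:
            s = s[heavy_mask[s]]
        sels[name] = s
    rows = []
    retained = []
    masses = None
    for g in range(len(conformers)):
        coords = conformers.coordinates[g]
        min_d = np.inf
        for a, b in pairs:
            ta = cKDTree(coords[sels[a]])
            d, _ = ta.query(coords[sels[b]], k=1)
            min_d = min(min_d, float(d.min()))
        if masses is None:
            masses = conformers.topology.masses()

        def wcom(s):
            m = masses[s]
            return (coords[s] * m[:, None]).sum(axis=0) / m.sum()

        d_ab = float(np.linalg.norm(wcom(sels["fab1"]) - wcom(sels["fab2"])))
        ok = (min_d >= cutoff) and (d_ab >= closed_fab_floor)
        if ok:
            retained.append(g)
        rows.append((g, *conformers.grid_angles[g], min_d, d_ab, ok))
    report = pd.DataFrame(
        rows,
        columns=["conformer", "torsion1", "torsion2", "torsion3", "min_interdomain", "d_ab", "retained"],
    )
    return np.array(retained, dtype=np.int64), report


def select_spread(
    conformers: ConformerSet,
    retained: np.ndarray,
    k: int,
    descriptors: np.ndarray,
) -> np.ndarray:
    """Pick k conformers spread over descriptor space (farthest-point sampling).

    ``descriptors`` is an (n_retained, 2) array of (D_ab, D_ac) per
    retained conformer.  The first two picks are the globally farthest
    pair; each further pick maximizes the minimum distance to the picks
    so far.  Ties break to the lowest index, so the result is
    deterministic given input order.  Returns indices into the original
    conformer set.
    """
    retained = np.asarray(retained, dtype=np.int64)
    descriptors = np.asarray(descriptors, dtype=np.float64)
    n = len(retained)
    if k > n:
        raise SpecError(f"requested {k} conformers but only {n} retained")
    if k == n:
        return retained.copy()
    if k <= 0:
        return retained[:0]
    if k == 1:
        return retained[:1]
    d = np.linalg.norm(descriptors[:, None, :] - descriptors[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)  # lowest indices on ties
    if i == j:  # all descriptors identical: fall back to leading indices
        i, j = 0, 1
    picks = sorted([int(i), int(j)])
    while len(picks) < k:
        min_d = d[:, picks].min(axis=1)
        min_d[picks] = -1.0
        picks.append(int(np.argmax(min_d)))
    return retained[np.array(sorted(picks))]
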