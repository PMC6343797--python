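"""Per-frame domain-geometry descriptors.

Implements the inter-domain descriptors used to characterize antibody
conformational ensembles: center-of-mass distances (D_ab between the
two Fabs, D_ac between a Fab and the Fc), three-point COM angles,
four-point torsions (e.g. the CH2/CH3 relative angle and dihedral),
best-fit-plane normal angles between sub-domains, the glycan-arm
bound/free distance, and 2D population histograms with modal-cluster
extraction (the population-shift readout).

All descriptors are invariant under global rotation and translation of
every frame.  Angles are reported in degrees; distances in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from igg_allostery.core_io import Trajectory
from igg_allostery.errors import ConfigurationError, DegenerateGeometryError

_EPS = 1e-12


@dataclass
class DescriptorSeries:
    """A named per-frame scalar series (units: ``"angstrom"`` or ``"degrees"``)."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise DegenerateGeometryError(f"descriptor {self.name!r} has non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Histogram2D:
    """Normalized 2D population histogram (density = fraction per bin)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class Mode:
    """A local density maximum with its integrated neighborhood population."""

    x: float
    y: float
    peak_density: float
    population: float


def com(traj: Trajectory, selection: np.ndarray, frame: int | None = None) -> np.ndarray:
    """Mass-weighted center of mass of a selection.

    Returns an (F, 3) array, or (3,) when ``frame`` is given.
    """
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ConfigurationError("COM of empty selection")
    m = traj.topology.masses()[selection]
    coords = traj.coordinates[:, selection, :]
    out = (coords * m[None, :, None]).sum(axis=1) / m.sum()
    return out[frame] if frame is not None else out


def com_distance_series(
    traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray, name: str = "com_distance"
) -> DescriptorSeries:
    """Per-frame Euclidean distance between two selection COMs (Å)."""
    d = np.linalg.norm(com(traj, sel_a) - com(traj, sel_b), axis=1)
    return DescriptorSeries(name, d, "angstrom")


def _points(traj: Trajectory, p) -> np.ndarray:
    """Resolve an anchor (int) or selection (array) to per-frame points."""
    if np.isscalar(p) or (isinstance(p, np.ndarray) and p.ndim == 0):
        return traj.coordinates[:, int(p), :]
    return com(traj, np.asarray(p))


def three_point_angle_series(
    traj: Trajectory, p1, p2, p3, name: str = "angle"
) -> DescriptorSeries:
    """Angle p1–p2–p3 (vertex at p2) in degrees, in [0°, 180°].

    The points may be single-atom anchors or selections (taken as COMs).
    """
    a = _points(traj, p1) - _points(traj, p2)
    b = _points(traj, p3) - _points(traj, p2)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    bad = (na < _EPS) | (nb < _EPS)
    if np.any(bad):
        raise DegenerateGeometryError(
            f"coincident points in angle {name!r} at frame {int(np.flatnonzero(bad)[0])}"
        )
    cosang = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
    return DescriptorSeries(name, np.degrees(np.arccos(cosang)), "degrees")


def dihedral_series(traj: Trajectory, p1, p2, p3, p4, name: str = "dihedral") -> DescriptorSeries:
    """Signed torsion p1–p2–p3–p4 in degrees, IUPAC convention.

    cis = 0°, sign by the right-hand rule about the p2→p3 axis; range
    (−180°, 180°] (the trans value is reported as +180°).
    """
    P1, P2, P3, P4 = (_points(traj, p) for p in (p1, p2, p3, p4))
    b1 = P2 - P1
    b2 = P3 - P2
    b3 = P4 - P3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nn1 = np.linalg.norm(n1, axis=1)
    nn2 = np.linalg.norm(n2, axis=1)
    bad = (nn1 < _EPS) | (nn2 < _EPS)
    if np.any(bad):
        raise DegenerateGeometryError(
            f"collinear arm in dihedral {name!r} at frame {int(np.flatnonzero(bad)[0])}"
        )
    b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(-y, x))
    ang[np.isclose(ang, -180.0)] = 180.0
    return DescriptorSeries(name, ang, "degrees")


def _plane_normals(coords: np.ndarray) -> np.ndarray:
    """Per-frame unit normal of the least-squares plane of (F, A, 3) coords.

    The normal is the singular vector of the centered coordinates with
    the smallest singular value; its sign is arbitrary.
    """
    centered = coords - coords.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear selections have two (near-)zero singular values
    if np.any(s[:, 1] < 1e-8 * (s[:, 0] + _EPS)):
        raise DegenerateGeometryError("collinear selection: best-fit plane undefined")
    return vt[:, 2, :]


def plane_normal_angle_series(
    traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray, name: str = "plane_angle"
) -> DescriptorSeries:
    """Angle between the best-fit plane normals of two selections.

    Folded to [0°, 90°] because the normal orientation is arbitrary.
    Each selection needs ≥3 non-collinear atoms.
    """
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if len(sel_a) < 3 or len(sel_b) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 atoms per selection")
    na = _plane_normals(traj.coordinates[:, sel_a, :])
    nb = _plane_normals(traj.coordinates[:, sel_b, :])
    cosang = np.clip(np.abs((na * nb).sum(axis=1)), 0.0, 1.0)
    return DescriptorSeries(name, np.degrees(np.arccos(cosang)), "degrees")


def principal_axis_angle_series(
    traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray, name: str = "axis_angle"
) -> DescriptorSeries:
    """Angle between the longest principal axes of two selections (θ descriptors).

    Folded to [0°, 90°]; the axis sign is arbitrary.
    """
    def axes(coords: np.ndarray) -> np.ndarray:
        centered = coords - coords.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        return vt[:, 0, :]

    na = axes(traj.coordinates[:, np.asarray(sel_a), :])
    nb = axes(traj.coordinates[:, np.asarray(sel_b), :])
    cosang = np.clip(np.abs((na * nb).sum(axis=1)), 0.0, 1.0)
    return DescriptorSeries(name, np.degrees(np.arccos(cosang)), "degrees")


def glycan_state_series(
    traj: Trajectory, tip_anchor: int, ref_anchor: int, bound_cutoff: float = 7.0
) -> tuple[DescriptorSeries, np.ndarray]:
    """Glycan tip–reference distance with per-frame bound/free labels.

    The glycan arm toggles between an Fc-bound state (distance peak near
    6 Å) and a free state (near 8 Å); the default cutoff of 7 Å is the
    midpoint.  A frame is labelled bound iff distance < ``bound_cutoff``.
    """
    d = np.linalg.norm(
        traj.coordinates[:, int(tip_anchor), :] - traj.coordinates[:, int(ref_anchor), :], axis=1
    )
    series = DescriptorSeries("glycan_distance", d, "angstrom")
    return series, d < bound_cutoff


def density_2d(
    series_x: DescriptorSeries | np.ndarray,
    series_y: DescriptorSeries | np.ndarray,
    bin_width: float = 2.5,
) -> Histogram2D:
    """Normalized 2D histogram of two equal-length descriptor series.

    Bin edges are aligned to multiples of ``bin_width`` so histograms of
    different systems share a grid.  Density is fraction per bin and
    sums to 1.
    """
    x = series_x.values if isinstance(series_x, DescriptorSeries) else np.asarray(series_x)
    y = series_y.values if isinstance(series_y, DescriptorSeries) else np.asarray(series_y)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) == 0:
        raise ValueError("empty descriptor series")
    lo_x = np.floor(x.min() / bin_width) * bin_width
    hi_x = np.ceil(x.max() / bin_width + 0.5) * bin_width
    lo_y = np.floor(y.min() / bin_width) * bin_width
    hi_y = np.ceil(y.max() / bin_width + 0.5) * bin_width
    x_edges = np.arange(lo_x, hi_x + 0.5 * bin_width, bin_width)
    y_edges = np.arange(lo_y, hi_y + 0.5 * bin_width, bin_width)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    return Histogram2D(x_edges, y_edges, counts / counts.sum())


def find_modes(
    hist: Histogram2D,
    min_density: float = 0.005,
    radius: float = 7.5,
) -> list[Mode]:
    """Extract modal clusters from a 2D histogram.

    A mode is a bin whose density is a strict-or-equal maximum over its
    8-neighborhood and at least ``min_density``.  Each mode's population
    is the summed density of bins whose centers lie within ``radius`` of
    the mode center, with bins contested by several modes assigned to
    the nearest one.  Modes are returned sorted by population
    (descending), ties broken by peak density.
    """
    d = hist.density
    nx, ny = d.shape
    padded = np.zeros((nx + 2, ny + 2))
    padded[1:-1, 1:-1] = d
    is_max = np.ones_like(d, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= d >= padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny]
    is_max &= d >= min_density
    peak_ij = np.argwhere(is_max)
    if len(peak_ij) == 0:
        return []
    xc, yc = hist.x_centers, hist.y_centers
    # merge plateau/adjacent peaks closer than one bin diagonal: keep the denser
    peaks = sorted(
        ((d[i, j], xc[i], yc[j]) for i, j in peak_ij), key=lambda t: -t[0]
    )
    bin_diag = np.hypot(xc[1] - xc[0] if len(xc) > 1 else 0.0,
                        yc[1] - yc[0] if len(yc) > 1 else 0.0)
    kept: list[tuple[float, float, float]] = []
    for pk in peaks:
        if all(np.hypot(pk[1] - q[1], pk[2] - q[2]) > bin_diag + 1e-9 for q in kept):
            kept.append(pk)

    centers = np.array([[p[1], p[2]] for p in kept])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    flat = np.stack([gx.ravel(), gy.ravel()], axis=1)
    dist = np.linalg.norm(flat[:, None, :] - centers[None, :, :], axis=2)  # bins × modes
    nearest = np.argmin(dist, axis=1)
    within = dist[np.arange(len(flat)), nearest] <= radius
    pops = np.zeros(len(kept))
    dens_flat = d.ravel()
    for b in np.flatnonzero(within):
        pops[nearest[b]] += dens_flat[b]
    modes = [
        Mode(x=float(p[1]), y=float(p[2]), peak_density=float(p[0]), population=float(pops[k]))
        for k, p in enumerate(kept)
    ]
    modes.sort(key=lambda m: (-m.population, -m.peak_density))
    return modes
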