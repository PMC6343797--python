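"""Synthetic antibody trajectories with planted statistical structure.

This module is a statistical fixture generator, not a simulator: it
emits Y-shaped pseudo-antibody trajectories (two Fab bodies + an Fc
body around a hinge, glycan arms, optional Fcγ-receptor bodies) whose
analysis-relevant statistics are *planted* and recorded, so that every
analysis stage can be validated by parameter recovery:

* conformational cluster populations in the (D_ab, D_ac) plane — e.g. a
  dominant apo mode near (70 Å, 70 Å) redistributing into two modes
  near (80 Å, 65 Å) and (65 Å, 80 Å) on antigen binding;
* pairwise motion correlations between domains, planted through a
  shared latent factor (x_i = √ρ·z + √(1−ρ)·ε_i), which hits the target
  correlation exactly in expectation;
* per-residue C=O bond-vector order, planted by uniform sampling in a
  cone whose half-angle β is solved from the closed-form uniform-cone
  order parameter S² = (cos β (1 + cos β) / 2)²;
* glycan-arm bound/free states at fixed tip–reference distances (6 Å
  bound / 8 Å free by default).

Each pseudo-domain is a rigid local geometry (tetrahedral core plus a
zig-zag backbone-like chain carrying CA, C and O atoms) translated per
frame; no bonds, energies or excluded volume are modelled.  The same
seed and spec always give a bit-identical trajectory, and the returned
ground-truth record suffices to recompute every planted statistic
independently of the analysis modules.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from igg_allostery.core_io import DomainMap, Topology, Trajectory
from igg_allostery.errors import SpecError

_CO_BOND = 1.23  # carbonyl C=O bond length, Å


@dataclass
class ClusterComponent:
    """One conformational cluster: weight, target (D_ab, D_ac) in Å, jitter σ."""

    weight: float
    d_ab: float
    d_ac: float
    sigma: float = 3.0


@dataclass
class CorrelationTarget:
    """Planted motion correlation ρ between two named domains."""

    domain_a: str
    domain_b: str
    rho: float
    amplitude: float = 2.0  # Å, std-dev of the planted displacement


@dataclass
class GlycanArmSpec:
    """Bound-state probability and bound/free tip distances of one glycan arm."""

    p_bound: float = 0.5
    bound_distance: float = 6.0
    free_distance: float = 8.0
    jitter: float = 0.15


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic antibody trajectory."""

    n_frames: int = 2000
    seed: int = 0
    n_res_per_domain: int = 8
    cluster_spec: list[ClusterComponent] = field(
        default_factory=lambda: [ClusterComponent(1.0, 70.0, 70.0, 3.0)]
    )
    correlation_spec: list[CorrelationTarget] = field(default_factory=list)
    #: per-domain target S² applied to every chain residue of that domain
    order_spec: dict[str, float] = field(
        default_factory=lambda: {"fab1": 0.85, "fab2": 0.85, "fc": 0.85, "hinge": 0.4}
    )
    glycan_spec: dict[str, GlycanArmSpec] = field(
        default_factory=lambda: {"glycan_a": GlycanArmSpec(), "glycan_b": GlycanArmSpec()}
    )
    include_receptor: bool = False
    include_antigen: bool = False

    def validate(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        w = sum(c.weight for c in self.cluster_spec)
        if abs(w - 1.0) > 1e-9:
            raise SpecError(f"cluster weights sum to {w}, not 1")
        for c in self.cluster_spec:
            if c.sigma < 0:
                raise SpecError("cluster jitter sigma must be >= 0")
            if c.d_ab <= 0 or c.d_ac <= 0:
                raise SpecError("cluster target distances must be positive")
            if c.d_ab > 2.0 * c.d_ac:
                raise SpecError(
                    f"infeasible geometry: D_ab={c.d_ab} exceeds arm span 2*D_ac={2 * c.d_ac}"
                )
        seen_domains: set[str] = set()
        for t in self.correlation_spec:
            if abs(t.rho) > 1:
                raise SpecError(f"|rho| > 1 for pair ({t.domain_a}, {t.domain_b})")
            for d in (t.domain_a, t.domain_b):
                if d in seen_domains:
                    raise SpecError(f"domain {d!r} appears in multiple correlation pairs")
                seen_domains.add(d)
        for dom, s2 in self.order_spec.items():
            if not 0.0 <= s2 <= 1.0:
                raise SpecError(f"target S2 for {dom!r} outside [0, 1]")
        for arm, g in self.glycan_spec.items():
            if not 0.0 <= g.p_bound <= 1.0:
                raise SpecError(f"bound-state probability for {arm!r} outside [0, 1]")


def cone_s2(beta: float) -> float:
    """Closed-form S² of a bond vector uniform over a cone of half-angle β."""
    c = np.cos(beta)
    return (c * (1.0 + c) / 2.0) ** 2


def cone_half_angle(s2_target: float) -> float:
    """Invert :func:`cone_s2` on [0, π/2] for a target S² in [0, 1]."""
    if not 0.0 <= s2_target <= 1.0:
        raise SpecError("S2 target outside [0, 1]")
    if s2_target >= 1.0:
        return 0.0
    if s2_target <= 0.0:
        return np.pi / 2
    return brentq(lambda b: cone_s2(b) - s2_target, 0.0, np.pi / 2, xtol=1e-12)


def _sample_in_cone(rng: np.random.Generator, beta: float, n: int) -> np.ndarray:
    """Unit vectors uniform (by solid angle) in a cone of half-angle β about +z."""
    cos_t = rng.uniform(np.cos(beta), 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


# ---------------------------------------------------------------------------
# Pseudo-domain local geometry
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates atoms and selections while laying out the topology."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.resids: list[int] = []
        self.resnames: list[str] = []
        self.chains: list[str] = []
        self.local: list[np.ndarray] = []
        self.selections: dict[str, list[int]] = {}
        self.anchors: dict[str, int] = {}
        self._next_resid = 1

    def atom(self, name: str, resid: int, resname: str, chain: str, pos) -> int:
        self.names.append(name)
        self.resids.append(resid)
        self.resnames.append(resname)
        self.chains.append(chain)
        self.local.append(np.asarray(pos, dtype=float))
        return len(self.names) - 1

    def new_resid(self) -> int:
        r = self._next_resid
        self._next_resid += 1
        return r

    def tag(self, selection: str, indices) -> None:
        self.selections.setdefault(selection, []).extend(
            [indices] if np.isscalar(indices) else list(indices)
        )


def _add_body(b: _Builder, chain: str, n_res: int, tags: list[str]):
    """Tetrahedral core + zig-zag CA/C/O chain; returns (atom idx, chain residue info).

    The chain residue info is a list of (resid, ca_idx, c_idx, o_idx).
    """
    idx: list[int] = []
    core = [(0.0, 0.0, 0.0), (3.0, 0.0, 0.0), (1.5, 2.6, 0.0), (1.5, 0.87, 2.45)]
    rid = b.new_resid()
    for k, p in enumerate(core):
        idx.append(b.atom(f"CB{k + 1}", rid, "COR", chain, p))
    residues = []
    for i in range(n_res):
        rid = b.new_resid()
        ca = np.array([1.5 * i, 4.5 + 0.8 * (i % 2), 1.0 * ((i % 3) - 1)])
        ca_i = b.atom("CA", rid, "ALA", chain, ca)
        c_i = b.atom("C", rid, "ALA", chain, ca + np.array([0.8, 0.4, 0.0]))
        o_i = b.atom("O", rid, "ALA", chain, ca + np.array([0.8, 0.4, _CO_BOND]))
        idx.extend([ca_i, c_i, o_i])
        residues.append((rid, ca_i, c_i, o_i))
    for t in tags:
        b.tag(t, idx)
    return idx, residues


def _masses_for(b: _Builder) -> np.ndarray:
    from igg_allostery.core_io import ATOMIC_MASSES, guess_element

    return np.array([ATOMIC_MASSES.get(guess_element(n), 12.011) for n in b.names])


def generate_antibody_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, DomainMap, dict]:
    """Generate a synthetic antibody trajectory with planted statistics.

    Per frame: a cluster label is drawn from the cluster weights; the
    Fab centers of mass are placed to realize that cluster's jittered
    (D_ab, D_ac) exactly (Fc fixed at the origin, the Fab pair in the
    xy-plane); correlated z-displacements from the shared-latent-factor
    construction are added to the domains named in the correlation spec;
    per-residue C=O vectors are drawn uniformly in the cone realizing
    the domain's target S²; glycan tips are set to the bound or free
    distance per arm.  After orienting the C=O vectors each domain is
    re-translated so its mass-weighted COM hits the target exactly.

    Returns (trajectory, domain map, ground-truth record).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    n_res = spec.n_res_per_domain

    fab1_idx, fab1_res = _add_body(b, "A", n_res, ["fab1"])
    fab2_idx, fab2_res = _add_body(b, "B", n_res, ["fab2"])
    fc_idx, fc_res = _add_body(b, "F", 2 * n_res, ["fc"])
    hinge_idx, hinge_res = _add_body(b, "H", max(3, n_res // 2), ["hinge"])

    # CH2 = first half of each "heavy chain half" of the Fc chain, CH3 = second
    q = len(fc_res) // 4
    for name, lo, hi in (
        ("ch2_a", 0, q),
        ("ch3_a", q, 2 * q),
        ("ch2_b", 2 * q, 3 * q),
        ("ch3_b", 3 * q, len(fc_res)),
    ):
        b.tag(name, [a for r in fc_res[lo:hi] for a in r[1:]])
    b.tag("cdr_loops", [a for r in fab1_res[:2] + fab2_res[:2] for a in r[1:]])

    # CH2/CH3 angle & dihedral anchors: four CA atoms spread along the Fc
    # chain, at mixed zig-zag phases so no three are collinear
    b.anchors["ch2ch3_p1"] = fc_res[1][1]
    b.anchors["ch2ch3_p2"] = fc_res[q][1]
    b.anchors["ch2ch3_p3"] = fc_res[2 * q + 1][1]
    b.anchors["ch2ch3_p4"] = fc_res[-1][1]

    # glycan arms: three one-atom sugar rings each; tip = GAL C1
    glycan_info = {}
    for arm, chain, sign in (("glycan_a", "Y", 1.0), ("glycan_b", "Z", -1.0)):
        ref_res = fc_res[2] if sign > 0 else fc_res[len(fc_res) // 2 + 2]
        arm_idx = []
        for k, resname in enumerate(("NAG", "MAN", "GAL")):
            rid = b.new_resid()
            arm_idx.append(b.atom("C1", rid, resname, chain, (0.0, 0.0, 0.0)))
        b.tag(arm, arm_idx)
        b.anchors[f"{arm}_tip"] = arm_idx[-1]
        b.anchors[f"{arm}_ref"] = ref_res[1]
        glycan_info[arm] = {"atoms": arm_idx, "ref": ref_res[1], "sign": sign}

    receptor_info = []
    if spec.include_receptor:
        for d in ("receptor_d1", "receptor_d2", "receptor_d3"):
            idx, res = _add_body(b, "R", n_res, [d, "receptor"])
            receptor_info.append((d, idx))
    antigen_idx: list[int] = []
    if spec.include_antigen:
        antigen_idx, _ = _add_body(b, "X", max(2, n_res // 2), ["antigen"])

    top = Topology.from_atoms(
        atom_names=b.names,
        residue_ids=np.array(b.resids),
        residue_names=np.array(b.resnames, dtype=object),
        chain_ids=np.array(b.chains, dtype=object),
    )
    masses = top.masses()
    local = np.array(b.local)

    domains = {
        "fab1": (np.array(fab1_idx), fab1_res),
        "fab2": (np.array(fab2_idx), fab2_res),
        "fc": (np.array(fc_idx), fc_res),
        "hinge": (np.array(hinge_idx), hinge_res),
    }
    for d, idx in receptor_info:
        domains[d] = (np.array(idx), [])
    if antigen_idx:
        domains["antigen"] = (np.array(antigen_idx), [])

    # --- per-frame sampling -------------------------------------------------
    F = spec.n_frames
    weights = np.array([c.weight for c in spec.cluster_spec])
    labels = rng.choice(len(weights), size=F, p=weights)
    d_ab = np.empty(F)
    d_ac = np.empty(F)
    for k, comp in enumerate(spec.cluster_spec):
        m = labels == k
        n_k = int(m.sum())
        d_ab[m] = comp.d_ab + comp.sigma * rng.standard_normal(n_k)
        d_ac[m] = comp.d_ac + comp.sigma * rng.standard_normal(n_k)
    # keep jittered geometry feasible (isoceles triangle inequality)
    d_ab = np.clip(d_ab, 1.0, 2.0 * d_ac - 1.0)

    # correlated displacement series, one shared latent factor per pair
    disp_series: dict[str, np.ndarray] = {}
    for t in spec.correlation_spec:
        for d in (t.domain_a, t.domain_b):
            if d not in domains:
                raise SpecError(f"correlation pair names unknown domain {d!r}")
        z = rng.standard_normal(F)
        a = np.sqrt(abs(t.rho))
        res_scale = np.sqrt(1.0 - abs(t.rho))
        disp_series[t.domain_a] = t.amplitude * (a * z + res_scale * rng.standard_normal(F))
        disp_series[t.domain_b] = t.amplitude * (
            np.sign(t.rho) * a * z + res_scale * rng.standard_normal(F)
        )

    # per-domain cone half-angles and per-frame C=O directions
    beta = {dom: cone_half_angle(s2) for dom, s2 in spec.order_spec.items()}
    co_dirs: dict[int, np.ndarray] = {}  # o_atom index -> (F, 3) unit vectors
    s2_targets_by_resid: dict[int, float] = {}
    for dom, (idx, res_list) in domains.items():
        if dom not in beta or not res_list:
            continue
        for rid, ca_i, c_i, o_i in res_list:
            co_dirs[o_i] = (
                _sample_in_cone(rng, beta[dom], F)
                if beta[dom] > 0
                else np.tile([0.0, 0.0, 1.0], (F, 1))
            )
            s2_targets_by_resid[rid] = spec.order_spec[dom]

    # glycan states and distances
    glycan_truth = {}
    for arm, g in spec.glycan_spec.items():
        bound = rng.random(F) < g.p_bound
        dist = np.where(bound, g.bound_distance, g.free_distance) + g.jitter * rng.standard_normal(F)
        glycan_truth[arm] = {"bound": bound, "distance": dist}

    # domain COM targets per frame
    h = np.sqrt(np.clip(d_ac**2 - (d_ab / 2.0) ** 2, 0.25, None))
    com_targets: dict[str, np.ndarray] = {
        "fc": np.zeros((F, 3)),
        "fab1": np.stack([+d_ab / 2.0, h, np.zeros(F)], axis=1),
        "fab2": np.stack([-d_ab / 2.0, h, np.zeros(F)], axis=1),
        "hinge": np.tile([0.0, 20.0, 0.0], (F, 1)),
    }
    for k, (d, idx) in enumerate(receptor_info):
        base = np.array([0.0, -25.0 - 15.0 * k, 0.0])
        com_targets[d] = base + 0.5 * rng.standard_normal((F, 3))
    if antigen_idx:
        com_targets["antigen"] = com_targets["fab1"] + np.array([6.0, 6.0, 0.0])
    for dom, series in disp_series.items():
        com_targets[dom] = com_targets[dom] + np.stack(
            [np.zeros(F), np.zeros(F), series], axis=1
        )

    # --- assemble coordinates ----------------------------------------------
    coords = np.empty((F, top.n_atoms, 3))
    for dom, (idx, res_list) in domains.items():
        loc = local[idx].copy()
        m = masses[idx]
        frame_local = np.tile(loc, (F, 1, 1))
        for rid, ca_i, c_i, o_i in res_list:
            if o_i in co_dirs:
                pos_in_dom = np.flatnonzero(idx == o_i)[0]
                c_pos = local[c_i]
                frame_local[:, pos_in_dom, :] = c_pos + _CO_BOND * co_dirs[o_i]
        com_local = (frame_local * m[None, :, None]).sum(axis=1) / m.sum()
        shift = com_targets[dom][:, None, :] - com_local[:, None, :]
        coords[:, idx, :] = frame_local + shift

    # glycan arms ride on the Fc: tip at the planted distance from the ref CA
    for arm, info in glycan_truth.items():
        atoms = glycan_info[arm]["atoms"]
        ref_i = glycan_info[arm]["ref"]
        sign = glycan_info[arm]["sign"]
        direction = np.array([sign, 0.3, 0.4])
        direction = direction / np.linalg.norm(direction)
        ref_pos = coords[:, ref_i, :]
        for k, a_i in enumerate(atoms):
            frac = (k + 1) / len(atoms)
            coords[:, a_i, :] = ref_pos + (frac * info["distance"])[:, None] * direction

    # frames are i.i.d. draws, so the consecutive-frame unwrap heuristic
    # does not apply to this fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        traj = Trajectory(top, coords)
    dmap = DomainMap(
        selections={k: np.array(sorted(set(v)), dtype=np.int64) for k, v in b.selections.items()},
        anchors=dict(b.anchors),
    )
    truth = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "labels": labels,
        "d_ab": d_ab,
        "d_ac": d_ac,
        "displacement_series": disp_series,
        "cone_half_angle": beta,
        "s2_targets_by_resid": s2_targets_by_resid,
        "glycan": glycan_truth,
    }
    return traj, dmap, truth


# ---------------------------------------------------------------------------
# Two-body complex with a deterministic contact schedule
# ---------------------------------------------------------------------------

@dataclass
class ContactScheduleEntry:
    """One scheduled residue pair and its target contact frequency."""

    resid_a: int
    resname_a: str
    resid_b: int
    resname_b: str
    frequency: float


def generate_two_body_complex(
    schedule: list[ContactScheduleEntry],
    n_frames: int,
    contact_distance: float = 2.0,
    apart_distance: float = 30.0,
) -> tuple[Trajectory, DomainMap]:
    """Antibody-Fc/receptor fixture realizing a contact schedule exactly.

    Each scheduled pair occupies its own spatial site (sites 50 Å apart,
    so pairs cannot interfere); the pair sits at ``contact_distance``
    for exactly ``round(frequency · n_frames)`` frames (the leading
    frames) and at ``apart_distance`` otherwise.  A residue may appear
    in several pairs; it then carries one atom per site.

    Selections in the returned map: ``fc`` (group A) and ``receptor``
    (group B).
    """
    if n_frames < 1:
        raise SpecError("n_frames must be >= 1")
    seen_pairs: set[tuple[int, int]] = set()
    for e in schedule:
        if not 0.0 <= e.frequency <= 1.0:
            raise SpecError(
                f"contradictory schedule: frequency {e.frequency} for "
                f"pair ({e.resid_a}, {e.resid_b})"
            )
        key = (e.resid_a, e.resid_b)
        if key in seen_pairs:
            raise SpecError(f"pair {key} scheduled twice")
        seen_pairs.add(key)

    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    coords = np.zeros((n_frames, 0, 3))
    cols: list[np.ndarray] = []
    sel_a: list[int] = []
    sel_b: list[int] = []

    def add_atom(resid, resname, chain, xyz_frames) -> int:
        names.append(f"C{sum(1 for r in resids if r == resid) + 1}")
        resids.append(resid)
        resnames.append(resname)
        chains.append(chain)
        cols.append(xyz_frames)
        return len(names) - 1

    for k, e in enumerate(schedule):
        site_y = 50.0 * k
        n_contact = int(round(e.frequency * n_frames))
        xa = np.tile([0.0, site_y, 0.0], (n_frames, 1))
        dx = np.full(n_frames, apart_distance)
        dx[:n_contact] = contact_distance
        xb = np.stack([dx, np.full(n_frames, site_y), np.zeros(n_frames)], axis=1)
        sel_a.append(add_atom(e.resid_a, e.resname_a, "F", xa))
        sel_b.append(add_atom(e.resid_b, e.resname_b, "R", xb))

    if not cols:
        # degenerate empty schedule: two far-apart placeholder atoms
        sel_a.append(add_atom(1, "ALA", "F", np.tile([0.0, 0.0, 0.0], (n_frames, 1))))
        sel_b.append(add_atom(2, "ALA", "R", np.tile([100.0, 0.0, 0.0], (n_frames, 1))))
    coords = np.stack(cols, axis=1)
    top = Topology.from_atoms(
        atom_names=names,
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        traj = Trajectory(top, coords)
    dmap = DomainMap(
        selections={
            "fc": np.array(sorted(set(sel_a)), dtype=np.int64),
            "receptor": np.array(sorted(set(sel_b)), dtype=np.int64),
        }
    )
    return traj, dmap


# ---------------------------------------------------------------------------
# Single-frame Y structure for the hinge torsion sweep
# ---------------------------------------------------------------------------

def make_y_structure(n_res_per_domain: int = 6) -> tuple[Trajectory, DomainMap]:
    """A single-frame Y-shaped structure with an explicit N/CA/C hinge.

    The hinge carries the atoms needed to define the three successive
    backbone torsions swept during conformer enumeration (ψ/φ-like
    quadruples around the central hinge residue); anchors ``torsion1_p1``
    … ``torsion3_p4`` name them.  The Fc sits below the hinge; the two
    Fab bodies branch off above it.
    """
    b = _Builder()
    fc_idx, _ = _add_body(b, "F", 2 * n_res_per_domain, ["fc"])
    fab1_idx, _ = _add_body(b, "A", n_res_per_domain, ["fab1"])
    fab2_idx, _ = _add_body(b, "B", n_res_per_domain, ["fab2"])

    # hinge backbone: residue 1 (C), residue 2 (N, CA, C), residue 3 (N, CA)
    r1 = b.new_resid()
    h_c1 = b.atom("C", r1, "GLY", "H", (0.0, 18.0, 0.0))
    r2 = b.new_resid()
    h_n2 = b.atom("N", r2, "GLY", "H", (0.6, 19.2, 0.4))
    h_ca2 = b.atom("CA", r2, "GLY", "H", (-0.3, 20.5, -0.2))
    h_c2 = b.atom("C", r2, "GLY", "H", (0.5, 21.8, 0.3))
    r3 = b.new_resid()
    h_n3 = b.atom("N", r3, "GLY", "H", (-0.2, 23.0, -0.4))
    h_ca3 = b.atom("CA", r3, "GLY", "H", (0.4, 24.3, 0.2))
    hinge_atoms = [h_c1, h_n2, h_ca2, h_c2, h_n3, h_ca3]
    b.tag("hinge", hinge_atoms)
    for name, a in zip(
        ("hinge_c1", "hinge_n2", "hinge_ca2", "hinge_c2", "hinge_n3", "hinge_ca3"), hinge_atoms
    ):
        b.anchors[name] = a

    top = Topology.from_atoms(
        atom_names=b.names,
        residue_ids=np.array(b.resids),
        residue_names=np.array(b.resnames, dtype=object),
        chain_ids=np.array(b.chains, dtype=object),
    )
    local = np.array(b.local)
    masses = top.masses()

    def place(idx, target):
        idx = np.array(idx)
        m = masses[idx]
        com = (local[idx] * m[:, None]).sum(axis=0) / m.sum()
        local[idx] += np.asarray(target) - com

    place(fc_idx, (0.0, 0.0, 0.0))
    place(fab1_idx, (35.0, 45.0, 0.0))
    place(fab2_idx, (-35.0, 45.0, 0.0))

    traj = Trajectory(top, local[None])
    dmap = DomainMap(
        selections={k: np.array(sorted(set(v)), dtype=np.int64) for k, v in b.selections.items()},
        anchors=dict(b.anchors),
    )
    return traj, dmap


# ---------------------------------------------------------------------------
# Named study conditions
# ---------------------------------------------------------------------------

def apo_spec(n_frames: int = 5000, seed: int = 0) -> SyntheticSpec:
    """Unbound antibody: one dominant mode at D_ab = D_ac = 70 Å."""
    return SyntheticSpec(
        n_frames=n_frames,
        seed=seed,
        cluster_spec=[ClusterComponent(1.0, 70.0, 70.0, 3.0)],
        correlation_spec=[CorrelationTarget("fab1", "fab2", 0.5)],
    )


def antigen_bound_spec(n_frames: int = 5000, seed: int = 0) -> SyntheticSpec:
    """Antigen-bound antibody: population shifts toward two new modes.

    The central (70, 70) Å mode loses weight to a Y-shaped mode near
    (D_ab, D_ac) = (65, 80) Å and a T-shaped mode near (80, 65) Å, the
    T-shaped mode keeping a population edge over the Y-shaped one and a
    rigidified hinge (target S² raised by 20 %).
    """
    return SyntheticSpec(
        n_frames=n_frames,
        seed=seed,
        cluster_spec=[
            ClusterComponent(0.45, 70.0, 70.0, 3.0),
            ClusterComponent(0.24, 65.0, 80.0, 3.0),  # Y-shaped, "cluster2"-like
            ClusterComponent(0.31, 80.0, 65.0, 3.0),  # T-shaped, "cluster3"-like
        ],
        correlation_spec=[CorrelationTarget("fab1", "fab2", 0.5)],
        order_spec={"fab1": 0.85, "fab2": 0.85, "fc": 0.85, "hinge": 0.48},
        glycan_spec={
            "glycan_a": GlycanArmSpec(p_bound=0.7),
            "glycan_b": GlycanArmSpec(p_bound=0.5),
        },
        include_antigen=True,
    )
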