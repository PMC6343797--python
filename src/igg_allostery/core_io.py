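"""Topology/trajectory data model, file I/O and domain-map resolution.

File parsing and writing (PDB, DCD, XTC) is delegated to MDAnalysis;
this module owns the light in-memory containers the analysis operators
work on, plus the YAML domain-map mini-language that binds named
selections (``fab1``, ``fc``, ``ch2_a`` ...) and single-atom anchors to
atom indices.

Units are Å everywhere; XTC coordinates (nm on disk) are converted on
read by MDAnalysis.  Inputs are assumed pre-unwrapped: periodic images
are out of contract, and only a max-displacement sanity warning between
consecutive frames guards against wrapped trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from igg_allostery.errors import ConfigurationError, TopologyError

logger = logging.getLogger(__name__)

#: residue names flagged as glycan sugars on read
GLYCAN_RESNAMES = frozenset(
    {"NAG", "BGLCNA", "MAN", "BMA", "AMAN", "BMAN", "GAL", "BGAL", "FUC", "AFUC", "SIA", "NDG"}
)

#: van der Waals radii in Å; glycan carbons are treated as aliphatic C
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_RADIUS = 1.70

#: standard atomic masses (u); unknown elements fall back to carbon
ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008, "P": 30.974}

#: consecutive-frame COM jumps beyond this suggest wrapped coordinates
MAX_FRAME_DISPLACEMENT = 20.0


def guess_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB-style atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass
class Topology:
    """Static atom/residue bookkeeping shared by all frames of a trajectory.

    Parameters
    ----------
    atom_ids : 1-based atom serial numbers, unique and strictly increasing.
    atom_names, elements, residue_ids, residue_names, chain_ids, is_glycan, radii :
        per-atom arrays, all of equal length.
    """

    atom_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    is_glycan: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.int64)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.is_glycan = np.asarray(self.is_glycan, dtype=bool)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        n = len(self.atom_ids)
        if n == 0:
            raise TopologyError("topology has zero atoms")
        for name in ("atom_names", "elements", "residue_ids", "residue_names",
                     "chain_ids", "is_glycan", "radii"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"field {name!r} length != number of atoms ({n})")
        if np.any(np.diff(self.atom_ids) <= 0):
            raise TopologyError("atom_ids must be unique and strictly increasing")
        if np.any(self.radii <= 0):
            raise TopologyError("atom radii must be positive")

    @classmethod
    def from_atoms(cls, atom_names, residue_ids, residue_names, chain_ids,
                   elements=None, is_glycan=None, radii=None) -> "Topology":
        """Build a topology from per-atom lists, filling derived fields.

        Elements are guessed from atom names if not given; glycan flags
        come from the sugar residue-name table; radii from the vdW table.
        """
        atom_names = np.asarray(atom_names, dtype=object)
        n = len(atom_names)
        residue_names = np.asarray(residue_names, dtype=object)
        if elements is None:
            elements = np.array([guess_element(a) for a in atom_names], dtype=object)
        if is_glycan is None:
            is_glycan = np.array([str(r).upper() in GLYCAN_RESNAMES for r in residue_names])
        if radii is None:
            radii = np.array([VDW_RADII.get(e, DEFAULT_RADIUS) for e in elements])
        return cls(
            atom_ids=np.arange(1, n + 1),
            atom_names=atom_names,
            elements=elements,
            residue_ids=residue_ids,
            residue_names=residue_names,
            chain_ids=chain_ids,
            is_glycan=is_glycan,
            radii=radii,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def masses(self) -> np.ndarray:
        """Per-atom masses (u) from the standard table; unknowns default to C."""
        out = np.empty(self.n_atoms)
        warned: set[str] = set()
        for i, e in enumerate(self.elements):
            if e not in ATOMIC_MASSES and e not in warned:
                logger.warning("unknown element %r: using carbon mass", e)
                warned.add(e)
            out[i] = ATOMIC_MASSES.get(e, ATOMIC_MASSES["C"])
        return out

    def residue_keys(self) -> list[tuple[str, int]]:
        """Per-atom (chain_id, residue_id) keys."""
        return list(zip(self.chain_ids, self.residue_ids))

    def residue_index(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Factorize atoms into residues.

        Returns (per-atom residue index, unique residue keys in order of
        first appearance).
        """
        keys = self.residue_keys()
        seen: dict[tuple[str, int], int] = {}
        idx = np.empty(self.n_atoms, dtype=np.int64)
        order: list[tuple[str, int]] = []
        for i, k in enumerate(keys):
            if k not in seen:
                seen[k] = len(order)
                order.append(k)
            idx[i] = seen[k]
        return idx, order

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])


@dataclass
class Trajectory:
    """A topology plus F × A × 3 coordinates in Å."""

    topology: Topology
    coordinates: np.ndarray
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.coordinates.shape[1]} != topology "
                f"size {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("coordinates contain non-finite values")
        if self.frame_index is None:
            self.frame_index = np.arange(self.n_frames)
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self._warn_if_wrapped()

    def _warn_if_wrapped(self) -> None:
        if self.n_frames < 2:
            return
        com = self.coordinates.mean(axis=1)
        jump = np.linalg.norm(np.diff(com, axis=0), axis=1).max()
        if jump > MAX_FRAME_DISPLACEMENT:
            warnings.warn(
                f"max consecutive-frame COM displacement {jump:.1f} Å exceeds "
                f"{MAX_FRAME_DISPLACEMENT} Å; trajectory may not be unwrapped",
                stacklevel=3,
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def with_coordinates(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.frame_index.copy())


@dataclass
class DomainMap:
    """Named atom-index selections and single-atom anchors (0-based indices)."""

    selections: dict[str, np.ndarray]
    anchors: dict[str, int] = field(default_factory=dict)

    def select(self, name: str) -> np.ndarray:
        """Return the atom indices of a named selection, failing fast if empty."""
        if name not in self.selections:
            raise ConfigurationError(f"no selection named {name!r}")
        sel = self.selections[name]
        if len(sel) == 0:
            raise ConfigurationError(f"selection {name!r} is empty")
        return sel

    def anchor(self, name: str) -> int:
        if name not in self.anchors:
            raise ConfigurationError(f"no anchor named {name!r}")
        return self.anchors[name]


# ---------------------------------------------------------------------------
# MDAnalysis bridge
# ---------------------------------------------------------------------------

def _to_mdanalysis(topology: Topology, coordinates: np.ndarray | None = None):
    import MDAnalysis as mda

    res_idx, res_keys = topology.residue_index()
    n_res = len(res_keys)
    chain_per_res = [k[0] for k in res_keys]
    resid_per_res = np.array([k[1] for k in res_keys])
    resname_per_res = np.empty(n_res, dtype=object)
    for i, ri in enumerate(res_idx):
        resname_per_res[ri] = topology.residue_names[i]

    seg_keys = list(dict.fromkeys(chain_per_res))
    seg_of = {c: i for i, c in enumerate(seg_keys)}
    res_seg = np.array([seg_of[c] for c in chain_per_res])

    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_keys),
        atom_resindex=res_idx,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(a) for a in topology.atom_names])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resids", resid_per_res)
    u.add_TopologyAttr("resnames", [str(r) for r in resname_per_res])
    u.add_TopologyAttr("segids", [str(c) if str(c) else "SYS" for c in seg_keys])
    u.add_TopologyAttr("chainIDs", [str(c)[:1] if str(c) else "A" for c in topology.chain_ids])
    u.add_TopologyAttr("masses", topology.masses())
    u.add_TopologyAttr("ids", topology.atom_ids)
    u.add_TopologyAttr("record_types", ["HETATM" if g else "ATOM" for g in topology.is_glycan])
    if coordinates is not None:
        u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
    return u


def _from_mdanalysis(atoms) -> Topology:
    names = atoms.names
    resnames = atoms.resnames
    try:
        elements = np.array(
            [e if str(e).strip() else guess_element(n) for e, n in zip(atoms.elements, names)],
            dtype=object,
        )
    except Exception:
        elements = None
    try:
        chains = atoms.chainIDs
    except Exception:
        chains = atoms.segids
    return Topology.from_atoms(
        atom_names=names,
        residue_ids=atoms.resids,
        residue_names=resnames,
        chain_ids=np.asarray(chains, dtype=object),
        elements=elements,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> Trajectory:
    """Read a PDB file into a single-frame trajectory.

    Atom order is preserved; HETATM sugar residues (NAG/BGLCNA/MAN/BMA/
    GAL/FUC ...) are flagged ``is_glycan``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TopologyError(f"could not parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise TopologyError(f"{path} contains zero atoms")
    top = _from_mdanalysis(u.atoms)
    coords = np.asarray(u.atoms.positions, dtype=np.float64)
    return Trajectory(top, coords[None])


def write_structure(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame of a trajectory as a PDB file."""
    u = _to_mdanalysis(traj.topology, traj.coordinates[frame])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(topology: Topology, path: str | Path) -> Trajectory:
    """Read a DCD or XTC multi-frame trajectory against a known topology.

    Frames come back in file order in Å (XTC nm→Å conversion is done by
    the reader).  An atom-count mismatch raises :class:`TopologyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _to_mdanalysis(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except ValueError as exc:
        raise TopologyError(f"trajectory {path} does not match topology: {exc}") from exc
    frames = []
    try:
        for ts in u.trajectory:
            frames.append(np.asarray(ts.positions, dtype=np.float64))
    except (OSError, EOFError) as exc:
        raise OSError(f"truncated trajectory {path}: read {len(frames)} frames: {exc}") from exc
    if frames and frames[0].shape[0] != topology.n_atoms:
        raise TopologyError(
            f"trajectory atom count {frames[0].shape[0]} != topology {topology.n_atoms}"
        )
    return Trajectory(topology, np.stack(frames))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame trajectory; format chosen by extension (.dcd/.xtc)."""
    import MDAnalysis as mda

    u = _to_mdanalysis(traj.topology, traj.coordinates[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f].astype(np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Domain-map resolution
# ---------------------------------------------------------------------------

def _parse_range_segment(segment: str) -> tuple[str | None, int, int]:
    """Parse one ``[chain:]first[-last]`` segment of a selection spec."""
    segment = segment.strip()
    chain: str | None = None
    if ":" in segment:
        chain, segment = segment.split(":", 1)
        chain = chain.strip()
    if "-" in segment:
        lo_s, hi_s = segment.split("-", 1)
        lo, hi = int(lo_s), int(hi_s)
    else:
        lo = hi = int(segment)
    if hi < lo:
        raise ConfigurationError(f"descending residue range {lo}-{hi}")
    return chain, lo, hi


def _resolve_selection(spec, topology: Topology) -> np.ndarray:
    """Materialize a selection spec string/list as a sorted atom-index array."""
    if isinstance(spec, str):
        segments = [s for s in spec.split(",") if s.strip()]
    else:
        segments = list(spec)
    mask = np.zeros(topology.n_atoms, dtype=bool)
    for seg in segments:
        chain, lo, hi = _parse_range_segment(str(seg))
        m = (topology.residue_ids >= lo) & (topology.residue_ids <= hi)
        if chain is not None:
            m &= np.array([str(c) == chain for c in topology.chain_ids])
        mask |= m
    return np.flatnonzero(mask)


def _resolve_anchor(spec: str, topology: Topology) -> int:
    """Resolve a ``chain:resid:atomname`` (or ``resid:atomname``) anchor."""
    parts = str(spec).split(":")
    if len(parts) == 3:
        chain, resid_s, atom = parts
    elif len(parts) == 2:
        chain, (resid_s, atom) = None, parts
    else:
        raise ConfigurationError(f"anchor spec {spec!r} not of form [chain:]resid:atomname")
    resid = int(resid_s)
    m = (topology.residue_ids == resid) & np.array(
        [str(a).strip() == atom.strip() for a in topology.atom_names]
    )
    if chain is not None:
        m &= np.array([str(c) == chain for c in topology.chain_ids])
    hits = np.flatnonzero(m)
    if len(hits) != 1:
        raise ConfigurationError(
            f"anchor {spec!r} resolves to {len(hits)} atoms (need exactly 1)"
        )
    return int(hits[0])


def resolve_domain_map(config: str | Path | dict, topology: Topology) -> DomainMap:
    """Resolve a YAML domain-map config against a topology.

    The config has two blocks::

        selections:
          fc: "443-633,1107-1322"
          ch3_a: "A:543-633"
        anchors:
          glycan_a_ref: "A:458:CA"

    Residue numbering is taken verbatim from the topology (1-based, as
    in the input files); any renumbering scheme lives in the config, not
    in code.  Empty selections fail fast at resolve time.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("domain-map config must be a mapping")
    selections: dict[str, np.ndarray] = {}
    for name, spec in (config.get("selections") or {}).items():
        sel = _resolve_selection(spec, topology)
        if len(sel) == 0:
            raise ConfigurationError(f"selection {name!r} ({spec!r}) matches no atoms")
        selections[name] = sel
    anchors: dict[str, int] = {}
    for name, spec in (config.get("anchors") or {}).items():
        anchors[name] = _resolve_anchor(spec, topology)
    return DomainMap(selections=selections, anchors=anchors)


def domain_map_to_yaml(topology: Topology, dmap: DomainMap) -> str:
    """Serialize a resolved domain map back to residue-range YAML."""
    out: dict = {"selections": {}, "anchors": {}}
    for name, sel in dmap.selections.items():
        pairs = sorted({(str(topology.chain_ids[i]), int(topology.residue_ids[i])) for i in sel})
        segments: list[str] = []
        start = prev = None
        chain_prev = None
        for chain, rid in pairs + [(None, None)]:  # type: ignore[list-item]
            if start is not None and (chain != chain_prev or rid != prev + 1):
                seg = f"{chain_prev}:{start}" if start == prev else f"{chain_prev}:{start}-{prev}"
                segments.append(seg)
                start = None
            if rid is not None and start is None:
                start = rid
                chain_prev = chain
            prev = rid if rid is not None else prev
        out["selections"][name] = ",".join(segments)
    for name, idx in dmap.anchors.items():
        out["anchors"][name] = (
            f"{topology.chain_ids[idx]}:{topology.residue_ids[idx]}:{topology.atom_names[idx]}"
        )
    return yaml.safe_dump(out, sort_keys=False)
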