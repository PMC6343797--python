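"""End-to-end analysis pipeline over one or more trajectory systems.

Orchestrates the per-system stages — domain-geometry descriptors, 2D
population histograms with modal clusters, QT conformational
clustering, DCCM, backbone S², interface contacts and network paths —
and writes a cross-system comparison report, mirroring the standard
four-complex comparison (apo / antigen-bound / receptor-bound /
ternary).  Every number in the report bundle is traceable to the
per-stage parameters echoed into the manifest, and all outputs are
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from igg_allostery import clustering, contacts, dynamics, geometry
from igg_allostery.core_io import (
    DomainMap,
    Trajectory,
    read_structure,
    read_trajectory,
    resolve_domain_map,
)
from igg_allostery.errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class SystemInput:
    """One named system: either in-memory objects or file paths."""

    name: str
    trajectory: Trajectory | None = None
    domain_map: DomainMap | None = None
    topology_path: str | None = None
    trajectory_path: str | None = None
    domain_map_path: str | None = None

    def load(self) -> tuple[Trajectory, DomainMap]:
        if self.trajectory is not None and self.domain_map is not None:
            return self.trajectory, self.domain_map
        if not (self.topology_path and self.domain_map_path):
            raise ConfigurationError(f"system {self.name!r}: missing inputs")
        single = read_structure(self.topology_path)
        traj = (
            read_trajectory(single.topology, self.trajectory_path)
            if self.trajectory_path
            else single
        )
        dmap = resolve_domain_map(self.domain_map_path, traj.topology)
        return traj, dmap


@dataclass
class AnalysisConfig:
    """Stage toggles and parameters for :func:`run_pipeline`."""

    systems: list[SystemInput]
    out_dir: str
    seed: int = 0
    descriptors: bool = True
    histogram: bool = True
    qt_clustering: bool = False
    dccm: bool = True
    order_params: bool = True
    contacts_stage: bool = False
    bin_width: float = 2.5
    mode_radius: float = 7.5
    mode_min_density: float = 0.005
    qt_cutoff: float = 4.0
    qt_max_clusters: int = 5
    contact_cutoff: float = 3.0
    contact_groups: tuple[str, str] = ("fc", "receptor")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        systems = [SystemInput(**s) for s in raw.pop("systems")]
        for s in systems:
            for p in (s.topology_path, s.trajectory_path, s.domain_map_path):
                if p and not Path(p).exists():
                    raise ConfigurationError(f"system {s.name!r}: missing file {p}")
        return cls(systems=systems, **raw)


def _descriptor_frame(traj: Trajectory, dmap: DomainMap) -> pd.DataFrame:
    """Standard descriptor set as one column per descriptor, one row per frame."""
    cols: dict[str, np.ndarray] = {}
    fab1, fab2, fc = dmap.select("fab1"), dmap.select("fab2"), dmap.select("fc")
    cols["d_ab"] = geometry.com_distance_series(traj, fab1, fab2, "d_ab").values
    cols["d_ac"] = geometry.com_distance_series(traj, fab1, fc, "d_ac").values
    cols["alpha_abc"] = geometry.three_point_angle_series(traj, fab1, fc, fab2, "alpha_abc").values
    cols["theta_ab"] = geometry.principal_axis_angle_series(traj, fab1, fab2, "theta_ab").values
    cols["theta_ac"] = geometry.principal_axis_angle_series(traj, fab1, fc, "theta_ac").values
    cols["phi_ab"] = geometry.plane_normal_angle_series(traj, fab1, fab2, "phi_ab").values
    cols["phi_ac"] = geometry.plane_normal_angle_series(traj, fab1, fc, "phi_ac").values
    if all(f"ch2ch3_p{i}" in dmap.anchors for i in (1, 2, 3, 4)):
        p = [dmap.anchor(f"ch2ch3_p{i}") for i in (1, 2, 3, 4)]
        cols["ch2ch3_angle"] = geometry.three_point_angle_series(
            traj, p[0], p[1], p[2], "ch2ch3_angle"
        ).values
        cols["ch2ch3_dihedral"] = geometry.dihedral_series(
            traj, p[0], p[1], p[2], p[3], "ch2ch3_dihedral"
        ).values
    for arm in ("glycan_a", "glycan_b"):
        if f"{arm}_tip" in dmap.anchors and f"{arm}_ref" in dmap.anchors:
            series, bound = geometry.glycan_state_series(
                traj, dmap.anchor(f"{arm}_tip"), dmap.anchor(f"{arm}_ref")
            )
            cols[f"{arm}_distance"] = series.values
            cols[f"{arm}_bound"] = bound.astype(float)
    return pd.DataFrame(cols)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run all enabled stages for every system; write a report bundle.

    Returns the manifest (also written as ``manifest.json``).  A failing
    stage is recorded in the manifest and later independent stages still
    run; the manifest's ``failures`` list is non-empty in that case.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "systems": [s.name for s in config.systems],
        "stages": {},
        "failures": [],
        "outputs": [],
    }
    comparison: dict = {"mode_tables": {}, "hinge_s2": {}, "qt_populations": {}}

    def record(stage: str, system: str, t0: float, params: dict) -> None:
        manifest["stages"].setdefault(stage, {})[system] = {
            "seconds": round(time.time() - t0, 3),
            **params,
        }

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest["outputs"].append(name)

    for system in config.systems:
        traj, dmap = system.load()
        desc: pd.DataFrame | None = None
        if config.descriptors:
            t0 = time.time()
            try:
                desc = _descriptor_frame(traj, dmap)
                save_csv(desc, f"{system.name}.descriptors.csv")
                record("descriptors", system.name, t0, {"n_frames": traj.n_frames})
            except Exception as exc:  # noqa: BLE001 - keep later stages running
                logger.exception("descriptor stage failed for %s", system.name)
                manifest["failures"].append({"stage": "descriptors", "system": system.name,
                                             "error": str(exc)})
        if config.histogram and desc is not None:
            t0 = time.time()
            try:
                hist = geometry.density_2d(
                    desc["d_ab"].to_numpy(), desc["d_ac"].to_numpy(), config.bin_width
                )
                modes = geometry.find_modes(
                    hist, min_density=config.mode_min_density, radius=config.mode_radius
                )
                table = [
                    {"d_ab": m.x, "d_ac": m.y, "population": m.population,
                     "peak_density": m.peak_density}
                    for m in modes
                ]
                comparison["mode_tables"][system.name] = table
                save_csv(pd.DataFrame(table), f"{system.name}.modes.csv")
                record("histogram", system.name, t0,
                       {"bin_width": config.bin_width, "mode_radius": config.mode_radius})
            except Exception as exc:  # noqa: BLE001
                logger.exception("histogram stage failed for %s", system.name)
                manifest["failures"].append({"stage": "histogram", "system": system.name,
                                             "error": str(exc)})
        if config.qt_clustering:
            t0 = time.time()
            try:
                aligned = clustering.superpose(traj, dmap.select("ch3_a"))
                result = clustering.qt_cluster(
                    aligned, dmap.select("fc"), config.qt_cutoff, config.qt_max_clusters
                )
                comparison["qt_populations"][system.name] = result.populations.tolist()
                save_csv(
                    pd.DataFrame({"cluster": range(result.n_clusters),
                                  "centroid_frame": result.centroids,
                                  "population": result.populations}),
                    f"{system.name}.clusters.csv",
                )
                record("qt_clustering", system.name, t0,
                       {"cutoff": config.qt_cutoff, "max_clusters": config.qt_max_clusters})
            except Exception as exc:  # noqa: BLE001
                logger.exception("clustering stage failed for %s", system.name)
                manifest["failures"].append({"stage": "qt_clustering", "system": system.name,
                                             "error": str(exc)})
        if config.dccm:
            t0 = time.time()
            try:
                node_atoms = [
                    i for i in range(traj.topology.n_atoms)
                    if str(traj.topology.atom_names[i]) == "CA"
                ]
                cm = dynamics.dccm(traj, np.array(node_atoms))
                df = pd.DataFrame(cm.values, index=cm.node_labels, columns=cm.node_labels)
                path = out / f"{system.name}.dccm.csv"
                df.to_csv(path, float_format="%.6g")
                manifest["outputs"].append(path.name)
                record("dccm", system.name, t0, {"n_nodes": len(node_atoms)})
            except Exception as exc:  # noqa: BLE001
                logger.exception("dccm stage failed for %s", system.name)
                manifest["failures"].append({"stage": "dccm", "system": system.name,
                                             "error": str(exc)})
        if config.order_params:
            t0 = time.time()
            try:
                pairs = dynamics.backbone_co_pairs(traj)
                profile = dynamics.order_parameters(traj, pairs)
                save_csv(
                    pd.DataFrame({"resid": profile.residue_ids, "s2": profile.s2}),
                    f"{system.name}.s2.csv",
                )
                hinge_resids = set(
                    int(traj.topology.residue_ids[i]) for i in dmap.select("hinge")
                )
                mask = np.isin(profile.residue_ids, sorted(hinge_resids))
                if mask.any():
                    comparison["hinge_s2"][system.name] = float(profile.s2[mask].mean())
                record("order_params", system.name, t0, {"n_bonds": len(pairs)})
            except Exception as exc:  # noqa: BLE001
                logger.exception("S2 stage failed for %s", system.name)
                manifest["failures"].append({"stage": "order_params", "system": system.name,
                                             "error": str(exc)})
        if config.contacts_stage:
            t0 = time.time()
            try:
                ga, gb = config.contact_groups
                table = contacts.contact_frequency(
                    traj, dmap.select(ga), dmap.select(gb), config.contact_cutoff
                )
                df = table.table.copy()
                df["frequency_pct"] = 100.0 * df.pop("frequency")
                save_csv(df, f"{system.name}.contacts.csv")
                record("contacts", system.name, t0, {"cutoff": config.contact_cutoff})
            except Exception as exc:  # noqa: BLE001
                logger.exception("contacts stage failed for %s", system.name)
                manifest["failures"].append({"stage": "contacts", "system": system.name,
                                             "error": str(exc)})

    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)
    manifest["outputs"].append("comparison.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
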