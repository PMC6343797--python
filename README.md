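# igg-allostery

Trajectory-analysis toolkit for studying allosteric communication in IgG
antibodies: how antigen binding at the Fab tips redistributes the
conformational ensemble of the Y-shaped molecule (two Fabs + Fc joined
by a flexible hinge), rigidifies the hinge, and propagates through the
Fc and its Asn297 glycans toward the Fcγ-receptor interface.

It is aimed at structural bioinformaticians analysing multi-frame
conformational ensembles (molecular-dynamics trajectories or generated
conformer sets) of antibodies and antibody–receptor complexes.

## What it computes

* **Domain geometry** — mass-weighted COM distances between domains
  (D_ab between the two Fabs, D_ac between a Fab and the Fc), COM
  angles α_abc, principal-axis angles θ, best-fit-plane normal angles
  φ, CH2/CH3 angle and dihedral from anchor atoms, and glycan-arm
  bound/free distances; plus 2D population histograms over
  (D_ab, D_ac) with modal-cluster extraction — the *population shift*
  readout of allostery.
* **Conformational clustering** — CH3-referenced Kabsch superposition,
  pairwise RMSD, greedy quality-threshold (QT) clustering with
  per-cluster population fractions, and cross-ensemble mean-RMSD
  matrices.
* **Dynamics** — the dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over residue nodes, and
  Lipari–Szabo generalized order parameters S² of backbone C=O bond
  vectors, S² = (3 Σ_ab ⟨u_a u_b⟩² − 1)/2.
* **Interfaces** — residue-pair contact frequencies (any heavy-atom
  pair within a cutoff, default 3 Å), accumulated contact maps, key
  binding residues (> 20 % frequency), and Shrake–Rupley solvent
  accessible surface area.
* **Dynamical networks** — residue graphs with contact-based edges
  weighted w = −log|C_ij|, Girvan–Newman communities at maximum
  modularity, and optimal/suboptimal source→sink paths (Dijkstra +
  Yen enumeration within a weight tolerance).
* **Hinge conformer enumeration** — sweeping three hinge backbone
  torsions in fixed steps (60° → 216 conformers) with the Fc fixed,
  clash filtering, and farthest-point selection of starting structures.
* **Synthetic data** — a generator of pseudo-antibody trajectories with
  *planted* cluster populations, motion correlations, bond-vector order
  and glycan states, so every stage can be validated by parameter
  recovery without MD data.

## Worked example

```python
from igg_allostery import synthetic, geometry, dynamics

spec = synthetic.antigen_bound_spec(n_frames=4000, seed=92)
traj, dmap, truth = synthetic.generate_antibody_trajectory(spec)

d_ab = geometry.com_distance_series(traj, dmap.select("fab1"), dmap.select("fab2"))
d_ac = geometry.com_distance_series(traj, dmap.select("fab1"), dmap.select("fc"))
hist = geometry.density_2d(d_ab.values, d_ac.values)
for m in geometry.find_modes(hist):
    print(f"mode at D_ab={m.x:5.1f} Å, D_ac={m.y:5.1f} Å  population {m.population:.2f}")
```

prints

```
mode at D_ab= 71.2 Å, D_ac= 68.8 Å  population 0.41
mode at D_ab= 78.8 Å, D_ac= 66.2 Å  population 0.30
mode at D_ab= 63.8 Å, D_ac= 78.8 Å  population 0.24
```

i.e. the antigen-bound ensemble keeps a central mode near
(70 Å, 70 Å) and develops a T-shaped mode (Fab–Fab wide, Fab–Fc
close) and a Y-shaped mode, with the T-shaped mode more populated —
the population-shift signature this package is built to detect.  The
same analyses are available from the shell via `igg-allostery`
(`synth`, `geometry`, `cluster`, `dccm`, `s2`, `contacts`, `network`,
`sweep`, `run`).

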