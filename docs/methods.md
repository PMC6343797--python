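# Methods

## The model and its readouts

An IgG antibody is treated as three quasi-rigid bodies — two Fabs and
the Fc — joined by a flexible hinge, decorated with two Asn297 N-glycan
arms and optionally bound to a three-domain Fcγ receptor.  Allosteric
communication is read out at four levels:

1. **Population shift.**  Per-frame descriptors locate each domain:
   the Fab–Fab COM distance D_ab, the Fab–Fc distance D_ac, the COM
   angle α_abc, principal-axis angles θ and plane-normal angles φ.
   The joint (D_ab, D_ac) density, binned at 2.5 Å, is summarized by
   its modal clusters; a ligand that redistributes weight among
   pre-existing modes (rather than creating new geometry) is acting
   allosterically.
2. **Conformational clustering.**  Frames are superposed on a
   reference sub-domain (conventionally CH3) by optimal proper
   rotation (Kabsch/SVD, reflections excluded) and clustered by greedy
   quality threshold: repeatedly take the frame with the most
   neighbors within an RMSD cutoff (default 4 Å) together with those
   neighbors, up to a maximum number of clusters (default 5); the
   remainder stays unassigned.  Ties go to the lowest frame index, so
   results are deterministic.
3. **Dynamics.**  The DCCM is the equal-time normalized covariance of
   residue-node fluctuations about their trajectory mean.  Backbone
   rigidity is the second-rank generalized order parameter of the C=O
   unit vector u,
   S² = (3(⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1)/2,
   which is 1 for a fixed orientation and 0 in the isotropic limit.
   Both assume global motion has been removed; a least-squares fit on
   a caller-chosen selection is applied first by default.
4. **Networks.**  Residue nodes (Cα; ring C1 for sugars) are joined by
   an edge when the residue pair stays in heavy-atom contact (4.5 Å in
   ≥ 75 % of frames, the dynamical-network convention) and weighted
   w = −log|C_ij|, so correlated residues are close.  Allosteric routes
   are minimum-weight paths (Dijkstra) plus all loop-free paths within
   a weight tolerance (default 20, k ≤ 25) enumerated Yen-style.
   Communities come from the Girvan–Newman hierarchy cut at maximum
   modularity; modularity is evaluated on connectivity only, because
   the −log|C| weights are distances, not affinities, and summing them
   as affinities would invert the meaning of "strongly connected".

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| histogram bin width | 2.5 | Å | resolves modes ~15 Å apart without fragmenting them |
| mode neighborhood radius | 7.5 | Å | integrates a mode's population; half the typical mode separation |
| QT RMSD cutoff / max clusters | 4.0 / 5 | Å / – | standard trajectory-clustering settings for Fc-scale domains |
| contact cutoff (interfaces) | 3.0 | Å | heavy-atom interface criterion |
| contact cutoff / persistence (network edges) | 4.5 / 0.75 | Å / – | dynamical-network convention |
| key-residue threshold | 0.20 | – | strict `>`: a pair at exactly 20 % is excluded |
| glycan bound/free cutoff | 7.0 | Å | midpoint of the 6 Å (bound) and 8 Å (free) tip-distance peaks |
| ASA probe / quadrature | 1.4 Å / 960 points | – | water probe; ≤ 1 % quadrature error |
| torsion sweep step | 60 | degrees | 6³ = 216 conformers over three hinge torsions |
| closed-Fab floor | 40 | Å | D_ab below this marks a collapsed, unusable start |

Hydrogens are excluded from contact detection by default (MD hydrogen
positions inflate contact counts); `heavy_only=False` restores the
literal all-atom reading.  RMSD is unweighted while COMs are
mass-weighted — the conventional asymmetry of trajectory tools.

## The synthetic generator

The generator emulates the *statistics* of an antibody ensemble, not
its physics.  Each pseudo-domain is a rigid tetrahedral core plus a
zig-zag chain whose residues carry CA, C and O atoms; domains are
translated per frame, never deformed.  Planting works as follows:

* **Clusters** — a per-frame label drawn from the component weights
  sets jittered target (D_ab, D_ac); the Fabs are placed in the
  xy-plane as the isoceles solution, so the planted distances are
  realized exactly (σ → 0 reproduces them to 10⁻⁶ Å).  A requested
  D_ab > 2·D_ac is geometrically infeasible and rejected.
* **Correlations** — the shared-latent-factor construction
  x_i = √ρ·z + √(1−ρ)·ε_i applied as z-axis displacements of the two
  named domains (amplitude 2 Å), giving exactly ρ in expectation and
  an analytically known standard error (1−ρ²)/√F.
* **Order** — C=O directions drawn uniformly (by solid angle) in a
  cone about +z whose half-angle β solves the closed form
  S² = (cos β (1+cos β)/2)²; after orienting the O atoms each domain is
  re-translated so its mass-weighted COM still hits the target exactly.
* **Glycans** — per-frame Bernoulli bound/free states place the arm
  tip at 6 or 8 Å (± 0.15 Å) from its Fc reference atom.
* **Contact schedules** — each scheduled residue pair occupies its own
  site (50 Å apart) and sits within contact distance for exactly
  `round(freq·F)` frames, so frequencies are recovered exactly.

The same seed and spec give bit-identical output, and the returned
ground-truth record suffices to recompute every planted statistic
without the analysis modules.

What the generator does **not** emulate: bonds, excluded volume,
solvent, correlated *rotational* domain motion, autocorrelated (slow)
dynamics, or realistic residue packing.  Passing recovery tests
therefore demonstrates estimator correctness — that each statistic is
computed right and converges at the expected rate — not that the
pipeline's defaults are optimal for any particular real trajectory.

Named study conditions: `apo_spec` plants one mode at
D_ab = D_ac = 70 Å with Fab–Fab correlation 0.5; `antigen_bound_spec`
shifts weight to a Y-shaped mode near (65, 80) Å and a slightly more
populated T-shaped mode near (80, 65) Å, raises hinge S² from 0.40 to
0.48 (+20 %), and biases one glycan arm toward the bound state.

## Numerical choices

* Dihedrals follow the IUPAC convention (cis = 0°, right-hand rule
  about the p2→p3 axis), reported in (−180°, 180°] with −180° folded
  to +180°; verified against an independent implementation.
* Plane normals are the smallest-variance principal axis of the
  selection's centered coordinates; plane and axis angles are folded
  to [0°, 90°] because the sign is arbitrary.  Collinear selections
  raise a degenerate-geometry error rather than returning noise.
* The θ (principal-axis) and φ (plane-normal) sub-domain angle
  constructions are this package's definitions for descriptors that
  are conventionally shown but rarely defined; both are documented
  here and isolated in their own functions so a different convention
  can be swapped in.
* Pairwise RMSD uses the Gram-matrix identity
  rmsd²(i,j) = (|x_i|² + |x_j|² − 2 x_i·x_j)/A on frames flattened to
  3A-vectors — one BLAS multiply instead of F² loops; negative
  round-off is clipped at zero.
* Zero-variance DCCM nodes produce a zeroed row/column with unit
  diagonal and a logged warning instead of NaNs.
* Mode extraction merges plateau peaks closer than one bin diagonal
  (keeping the denser) and assigns contested bins to the nearest mode;
  because populations are integrated over a fixed 7.5 Å neighborhood,
  they truncate Gaussian tails symmetrically, so planted weights are
  compared as fractions of the assigned population.
* Shrake–Rupley uses a golden-spiral lattice fixed in the lab frame;
  ASA is therefore rotation-invariant only to quadrature error
  (≲ 0.5 % at 960 points).
* Torsion sweep: rotations are applied in torsion order 1→2→3 (they
  do not commute); with nested mobile sets each conformer measures
  back its grid triple to 10⁻⁶ degrees, and the fixed Fc is
  bit-identical across all conformers.
* Farthest-point conformer selection starts from the globally
  farthest descriptor pair; all ties break to the lowest index.
* Trajectories are assumed unwrapped; a > 20 Å COM jump between
  consecutive frames triggers a warning, nothing more.

## Problem sizes

The validation suite and the reproduction script run on synthetic
ensembles of ~130–190 atoms: 2×10⁴ frames for cluster-population
recovery, 10⁴ for correlation recovery, 5×10³ for order parameters and
the hinge-rigidification readout, 2×10³ frames for QT clustering
(whose pairwise stage is O(F²)), 10³ for contact schedules, and 4×10³
per system for the two-system pipeline comparison.  These sizes put
every planted parameter's sampling error well inside its test
tolerance while keeping the whole suite in the tens of seconds.

## Known limitations

* Hydrogen-bond geometry (donor–acceptor–angle) is not implemented;
  interface persistence is approximated by heavy-atom contact
  frequency throughout.
* Community detection recomputes the full Girvan–Newman hierarchy;
  fine for residue-level graphs (≲ 10³ nodes), not for atom-level ones.
* `cross_ensemble_mean_rmsd` is O(F²) per ensemble pair; use the
  stride argument (recorded in the metadata) for long trajectories.
* Pipeline DCCM/S² stages assume Cα/C/O atom naming; exotic topologies
  need explicit node and bond-pair lists via the library API.
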