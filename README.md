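# hingescan

Hinge-residue detection for two-domain proteins from coarse-grained
normal modes.

Many proteins move as two quasi-rigid domains pivoting about a small set
of residues — a hinge. Hinge residues barely move in space, yet they
absorb most of the elastic strain of the interdomain motion, and
mutating them can disrupt a protein's functional dynamics without
touching its fold or its binding interfaces. The classic case is a
two-domain metalloproteinase inhibitor whose receptor-mediated
endocytosis depends on an interdomain "wirecutter" motion hinged on a
pair of residues joined by a single hydrogen bond. `hingescan`
implements the computational pipeline for finding such residues in any
Cα structure:

1. **Elastic network model (ENM).** One bead per residue; pairwise
   springs with stiffness set by sequence separation (`k_bond` for chain
   neighbours), distance (`c/r⁶` within a cutoff), secondary structure
   (helix 1–4 contacts and β-bridges scaled by `γ_sse`) and disulfide
   bonding (`k_ss`).
2. **Normal mode analysis.** Eigendecomposition of the 3N×3N Hessian.
   The six null-frequency modes are rigid-body translation/rotation;
   mode 7 (1-based over all modes) is the softest internal motion.
3. **Per-residue profiles** for a unit-amplitude mode *e* with
   eigenvalue λ:
   - Cα fluctuation `f_i = |e_i|² / λ` (absolute motion),
   - deformation energy `d_i = ½ Σ_j ½ k_ij (r̂_ij·(e_i − e_j))²`
     (local strain; totals λ/2),
   - collectivity `κ = exp(−Σ p_i ln p_i)/N`, `p_i ∝ |e_i|²`
     (how global the motion is).
4. **Hinge calling.** Min-max normalize and superpose the two profiles;
   residues with high deformation energy (`≥ τ_def`) *and* low
   fluctuation (`≤ τ_fluct`) are merged into contiguous regions;
   residues inside helix/sheet spans are excluded from mutational
   candidacy (mutating folded secondary structure risks misfolding).
5. **Hydrogen-bond persistence.** Candidate residues are screened for
   N/O heavy-atom contacts under 3.2 Å, and each bond is tracked along a
   sinusoidal interpolation of the structure through one full period of
   the mode: persistence is the fraction of intermediate conformations
   in which the bond survives.
6. **Trajectory PCA cross-check.** Any multi-model Cα trajectory is
   superposed on its first frame (Kabsch fit) and the coordinate
   covariance diagonalized; per-residue contributions of the top
   components should corroborate the mode picture.

A seeded synthetic-data module generates ideal helices, two-domain
dumbbells with a known hinge, and mode-sampled trajectories with known
covariance, so the whole pipeline is testable end to end with planted
ground truth and no downloads.

## Worked example

Generate a two-domain dumbbell with a four-residue linker (residues
31–34) and run the full pipeline:

```sh
$ hingescan synth --kind dumbbell --n 30 --n-linker 4 --seed 1 --out dumbbell.pdb
linker span: 31-34
$ hingescan run --structure dumbbell.pdb --out analysis --seed 1
INFO model: 64 beads, 1 disulfides
INFO 192 modes, 6 rigid; analysing mode 7
INFO 1 hinge regions, 1 candidate residues (thresholds {'tau_def': 0.4, 'tau_fluct': 0.25, 'max_gap': 1})
```

The run finds exactly six rigid-body modes, analyses mode 7 and calls
the hinge inside the constructed linker. `analysis/modes.tsv` shows the
spectrum — six numerically null eigenvalues, then the soft interdomain
mode with high collectivity:

```
mode  eigenvalue        frequency        rigid  collectivity
6     5.894445582e-14   2.427847932e-07  True
7     4.241201621e-06   0.002059417787   False  0.7109640124
```

`analysis/hinge_report.json` names the candidate and the threshold-free
score ranking `S_i = def_i·(1 − fluct_i)` confirms it dominates:

```
candidates: ['A32']    scores: A32 0.927, A31 0.307, A34 0.279
```

The same pipeline on the bundled synthetic two-domain-inhibitor
stand-in (planted lysine→backbone-carbonyl bond at the hinge flank)
demonstrates the H-bond stage:

```python
from hingescan import *
from hingescan.synthetic import make_two_domain_inhibitor

tw = make_two_domain_inhibitor(seed=0)
model = extract_calpha(tw.structure)
build_force_constants(model)
modes = compute_modes(build_hessian(model))
report = hinge_report(model, modes)
bond = detect_hbonds(tw.structure, model, {tw.donor_resnum, tw.acceptor_resnum})[0]
traj = mode_trajectory(model, modes, 7)       # max Cα RMSD 2 Å from reference
p = hbond_persistence(bond, traj)
print(report.candidate_residues)
print(f"{bond.donor_residue}({bond.donor_atom}) -> "
      f"{bond.acceptor_residue}({bond.acceptor_atom}): "
      f"{bond.distance:.2f} Å, persistence {p:.2f}")
```

prints

```
['A55', 'F56', 'A57', 'A58', 'A59', 'A60']
K19(NZ) -> F56(O): 2.90 Å, persistence 1.00
```

— the candidate list covers the hinge, the planted phenylalanine flank
residue is among the candidates, and its 2.90 Å bond to the lysine
side-chain nitrogen survives every intermediate conformation of the
interdomain mode (persistence 1.0).

To analyse a crystallographic structure, point `--structure` at a PDB
file and set the chain and mature-numbering offset in a config file
(see `examples/real_structure.cfg`); an optional `--trajectory`
multi-model PDB adds the PCA cross-check.

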