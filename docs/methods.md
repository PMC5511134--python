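# Methods

## Model

`hingescan` works at Cα resolution. A protein is reduced to one bead
per residue and its dynamics approximated by a harmonic elastic network:
the potential is `E = ½ Σ_pairs k_ij (|r_ij| − |r⁰_ij|)²` over all bead
pairs with non-zero spring constant. The Hessian of this potential at
the reference structure has 3×3 blocks `H_ij = −k_ij r̂_ij r̂_ijᵀ`
(off-diagonal) and `H_ii = Σ_j k_ij r̂_ij r̂_ijᵀ`, which makes every
block row sum to zero (translation invariance) and the matrix positive
semidefinite for any non-negative spring set. Normal modes are its
eigenpairs; masses are uniform (no mass weighting), so the reported
"frequency" is `√λ` in model units and mode shapes are exactly the
eigenvectors. The harmonic picture is only trustworthy for small
displacements around the reference; amplitudes here are geometric
probes, not thermal ensembles.

### Spring constants

| parameter | default | role |
|---|---|---|
| `k_bond` | 1000 energy/Ų | virtual bond between chain neighbours (\|i−j\| = 1) |
| `c` | 10⁴ energy·Å⁴ | non-bonded distance term `k = c/r⁶` within `r_cut` |
| `r_cut` | 15 Å | non-bonded cutoff |
| `γ_sse` | 5 | multiplier on the distance term for helix 1–4 pairs (2 ≤ \|i−j\| ≤ 4 inside one helix span) and β-bridges |
| `r_bridge` | 5.5 Å | max Cα–Cα distance for a β-bridge (both beads in sheet spans, \|i−j\| ≥ 2) |
| `k_ss` | 500 energy/Ų | disulfide-bridged pair, distance independent |

Precedence when rules overlap: chain bond > disulfide > secondary
structure > plain distance term. The absolute energy scale is
arbitrary and cancels in every normalized quantity; only the *ratios*
of the constants matter, and the defaults encode the usual coarse-
grained hierarchy (covalent ≫ disulfide ≫ packing contacts). All
constants are configurable per run, and every correctness test in the
suite is parameter-independent (conservation laws, oracles,
invariances), so changing the force field cannot silently break the
mathematics.

### Rigid-mode detection

A connected network in generic position has exactly six zero
eigenvalues. Modes are flagged rigid when `λ < zero_tol · λ_max` with
`zero_tol = 1e-12`. This threshold is deliberately far below the
conventional 10⁻⁶: with `k_bond` three to six orders of magnitude above
the non-bonded constants the spectrum spans ~10⁶, and a floppy
two-domain structure's genuine hinge modes can sit at 10⁻¹¹–10⁻⁹
relative to `λ_max`, while the numerical null space of a dense
symmetric eigensolver sits near machine precision (~10⁻¹⁶ relative) for
the problem sizes targeted here (N ≲ 1000, dense `scipy.linalg.eigh`).
1e-12 separates the two populations by at least four orders of
magnitude on every structure we generate. More than six near-null
modes triggers a warning, not an error — collinear or coplanar bead
arrangements legitimately produce extra mechanisms.

Mode indices are 1-based over *all* modes, so the first internal mode
of a generic structure is mode 7. Eigenvector signs are fixed by
making the largest-magnitude component positive; every sign-dependent
quantity downstream is also tested to be sign-invariant.

## Per-residue descriptors

For a unit-norm eigenvector `e` with eigenvalue λ:

* **Fluctuation** `f_i = |e_i|²/λ`. Summed over all internal modes
  this reproduces the diagonal 3×3-block traces of the Hessian
  pseudo-inverse — a test uses `numpy.linalg.pinv` as the independent
  oracle.
* **Deformation energy** `d_i = ½ Σ_j ½ k_ij (r̂_ij·(e_i − e_j))²`:
  the axis-projected (harmonic-consistent) pair energy, split evenly
  between the two beads of each spring. The axis-projected form is
  chosen over the full distance-change variant because it closes
  exactly against the Hessian: `Σ_i d_i = λ/2` for a unit-amplitude
  mode, which the suite asserts to 1e-9 relative. Rigid modes return
  an all-zero profile flagged as rigid rather than an error.
* **Collectivity** `κ = N⁻¹ exp(−Σ p_i ln p_i)` with `p_i` the
  normalized squared amplitude, `0·ln 0 := 0`; κ = 1 for a uniform
  mode, 1/N for a single-bead mode.

## Mode-interpolated conformations

Intermediate structures along a mode follow
`x(φ) = x⁰ + A sin(φ) e` over one full period, 21 frames by default
(the quarter-period frames then hit `sin φ = ±1` exactly, so the
maximum Cα RMSD from the reference equals `A/√N` to machine precision,
and frame 0 *is* the reference). The amplitude is calibrated so that
the maximum RMSD is 2.0 Å by default: large enough to break marginal
contacts, small enough that the harmonic approximation and the
rigid-residue rule below stay meaningful. No thermal (kT) scaling is
attempted; persistence results should be read as functions of this
amplitude, which the run manifest records.

## Hinge calling

Deformation-energy and fluctuation profiles are min-max normalized
(monotone, idempotent; a constant profile is an error) and superposed.
Residue *i* qualifies iff `def_i ≥ τ_def` **and** `fluct_i ≤ τ_fluct`;
runs of qualifying residues separated by at most `max_gap`
non-qualifying residues merge into one region. Defaults
`τ_def = 0.4`, `τ_fluct = 0.25`, `max_gap = 1`. Thresholds on min-max
scores are inevitably somewhat arbitrary, so every report also carries
the threshold-free ranking `S_i = def_i (1 − fluct_i)` and always
prints the thresholds and region count it used. Residues inside
helix/sheet spans are excluded from candidacy (mutating structured
residues risks misfolding rather than altered dynamics); regions
entirely consumed by the exclusion are still reported as
detected-but-excluded.

Secondary structure is taken from HELIX/SHEET records of the input
file, or from a four-column override table; no DSSP-style recomputation
is performed.

## Hydrogen bonds

Heavy-atom criterion only: any N/O pair across two residues at least
two apart in sequence, strictly under 3.2 Å. No donor–H–acceptor angle
is evaluated — the pipeline never places hydrogens, and at Cα
resolution a geometric distance is the honest statement of what is
known. Along a mode trajectory each heavy atom translates rigidly with
its residue's Cα displacement; side-chain reorientation is therefore
invisible, which is a stated limitation, not an approximation error —
persistence numbers measure whether the *backbone geometry* of the two
residues stays compatible with the bond.

## Trajectory PCA

Frames are least-squares fitted onto the first frame (Kabsch SVD; a
hand-written Horn quaternion method serves as the independent oracle in
the tests; collinear frames are rejected as degenerate). The
covariance is taken about the trajectory *mean* — the reference frame
only defines the fit, and with F frames the normalization is F−1. The
eigenvalue sum equals the total coordinate variance (asserted), and
per-residue contributions are the squared per-residue norms of the unit
component vectors, summing to one. Three components are retained by
default. PCA here is Cα-only.

## Synthetic data

The generators exist to give every stage a testable ground truth:

* **Helix** — ideal α-geometry (rise 1.5 Å, 100°/residue, radius
  2.3 Å) with idealized backbone N/C/O placements and an annotated
  HELIX span; optional per-coordinate Gaussian noise. Used as the
  "generic compact fold" for rigid-mode counting.
* **Dumbbell** — two compact domains, each grown as a confined
  self-avoiding walk with uniform 3.8 Å virtual bonds (an unordered
  packing would thread long stiff bonds through the domain and
  concentrate spurious strain on them), joined by a helically offset
  non-planar linker (a straight or planar linker has exact
  zero-stiffness transverse mechanisms that corrupt the null space),
  plus one interdomain disulfide brace off the linker axis so that
  torsion does not become a near-mechanism. The linker span is the
  planted hinge. Across 60 random realisations ~96 % of called
  candidates fall within the linker ± 1 residue; the rare leakage is
  one bead further into the domain neck, which is genuinely soft —
  the formal linker span slightly understates the physical hinge.
* **Mode-sampled trajectories** — frames `x⁰ + Σ_k a_k e_k`,
  `a_k ~ N(0, σ_k²)` i.i.d. per frame, so the population covariance is
  `Σ σ_k² e_k e_kᵀ` exactly; used for PCA parameter recovery (500
  frames recovers a planted mode direction with |cos| > 0.99 and its
  variance within 15 %).
* **Two-domain inhibitor stand-in** — a dumbbell dressed with backbone
  carbonyl oxygens, helix/sheet spans, three disulfides and one planted
  lysine-NZ → backbone-carbonyl bond (2.9 Å) between two hinge-flank
  residues of the larger domain. It is entirely synthetic — labelled
  as such in code and docstrings — and stands in for a real two-domain
  crystal structure in the end-to-end tests: what those tests
  demonstrate is that the *pipeline* finds planted hinges and preserved
  bonds, not that any particular real protein behaves this way.

What the synthetic data does **not** emulate: real packing density and
contact order, side-chain geometry, crystallographic noise,
B-factor-correlated disorder, and solvent effects. Passing tests
therefore validate the mathematics and the detection logic, not
force-field realism on real proteins.

## Numerical choices and degenerate inputs

* Dense eigensolvers throughout (N ≤ ~1000); no sparse/iterative path.
* Altloc resolution: highest occupancy, file order breaking ties.
* Residues with insertion codes must be mapped through explicit
  numbering overrides; there is no silent guess.
* Coincident beads (< 10⁻⁶ Å) and disconnected networks are errors
  naming the offending beads/components.
* Determinism: all randomness flows through seeded
  `numpy.random.default_rng`; eigenvector and PC signs are fixed;
  pipeline outputs are byte-identical across reruns of the same config
  and seed (tables use a fixed float format, JSON is key-sorted, the
  manifest carries no timestamps).
* Problem sizes in the test suite and acceptance script (30–100 residue
  structures, 500–2000-frame trajectories) keep the full suite in a few
  seconds while leaving every conservation law and recovery property
  sharp.

## Known limitations

* The force-field constants are a documented convention, not a fit;
  per-residue profiles on real proteins will match other ENM codes
  qualitatively, not numerically.
* Hinge thresholds operate on min-max scores and are sensitive to
  profile outliers; the score ranking is the robust output.
* H-bond persistence ignores side-chain motion by construction.
* Single-mode analysis: multi-mode consensus is left to repeated runs.
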