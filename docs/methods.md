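# Methods

This note records the models implemented in `framefold`, the numerical
choices behind them, and what the synthetic test conditions do and do
not establish.

## Coarse-grained representation and frames

Each nucleotide is reduced to three beads — P, C4', and the glycosidic
nitrogen (N9 for A/G, N1 for U/C; the unknown base 'N' aliases U) — and
a rigid frame `T_i = (R_i, t_i)` with `det R_i = +1` (asserted to 1e-6
in every constructor).  The local 3-atom template of each base type is
the (P, C4', N) triad of that nucleotide in the package's ideal A-form
helix, centered on its centroid and expressed in its own
symmetric-orthogonalized frame.  Frames are fitted to observed triads by
Kabsch superposition (SVD with determinant correction), which realizes
SVD orthogonalization as a concrete least-squares algorithm; a
Gram-Schmidt construction exists only as a test comparator.  Collinear
or coincident triads raise a degenerate-geometry error.

## The ideal A-form helix

Stems are generated by a helical symmetry of 32.7 degrees twist and
2.548 A rise per step, with the complementary strand as the dyad image
(rotation by pi about an axis perpendicular to the helix axis).  The
nucleotide geometry comes from the idealized chemical-component
dictionary monomers bundled with biotite, grafted onto one shared
sugar-phosphate backbone.  Because no published coordinate set is used
for the placement, the rigid placement of the nucleotide inside the
helix frame — together with four backbone torsion adjustments and
per-base glycosidic rotations — is solved once by least squares against:
O3'(i)-P(i+1) backbone continuity (target 1.6 A) on both strands,
canonical Watson-Crick hydrogen-bond distances and base coplanarity for
A-U and G-C across the dyad, weak A-form priors (P radius 9.4 A,
C1'-C1' 10.4 A, P-P step 5.9 A), and steric hinges between stacked and
paired residues.  The converged parameters are pinned in the source
(`geometry._PLACEMENT_X`); `geometry.solve_helix_placement()` re-derives
them.  The realized geometry has O3'-P = 1.86 A, P-P steps of 5.89 A,
hydrogen-bond distances within a few hundredths of their targets, and
no steric overlaps under the package's contact radii.  At a 2.548 A
rise, perfect 1.6 A connectivity, coplanar pairs, and fully relaxed
stacking cannot be satisfied simultaneously by a rigid nucleotide; the
pinned solution is the documented compromise.

Loop regions are schematic by design: hairpin loops bridge the stem
ends on a circular arc sized for ~6 A backbone steps, open regions walk
with a gentle turn, and successive helices in open regions are placed
with a configurable turn (default 120 degrees, which fixes the
two-helix-junction fixture geometry).  Loop placements are finite,
deterministic, and connective, but not sterically relaxed; nothing
downstream depends on loop realism because references enter the folding
stage only through their own measured restraints.

## Losses

`L_e2e = 1.5 L_FAPE + 0.6 L_dist`.  FAPE enumerates all L frames
against all 3L bead atoms expressed through their own frames, with
clamp `d_cut = 30 A` and `eps = 1e-3` inside the square root (a perfect
prediction scores sqrt(eps) per term).  FAPE is reported as the mean
over terms so the 1.5/0.6 weights stay scale-stable across lengths; a
`sum` mode is a config switch.  The inter-N distance loss is a
cross-entropy over 38 bins (36 uniform on [2, 40] A plus the two
out-of-range bins), summed over ordered pairs with the diagonal masked.
The geometry loss sums the six per-term cross-entropies with weight 1.0
for distances and 0.5 for dihedrals.  Probabilities are clipped at
1e-12 before logs.  All losses run on the package's reverse-mode
autodiff core and are gradient-checked against finite differences.

## Geometry terms and binning

Distances use half-open bins `[edge, edge + width)` with a 1e-9 snap so
float-inexact edges land on their right bin; values below 2 A take the
first extra bin, values at or beyond the term's maximum M take the
last.  Dihedrals use 36 uniform bins over (-pi, pi] plus one extra bin
taken whenever the quadruple's central virtual bond is at or beyond its
M — C4'-C4' (M = 24 A) for P-C4'-C4'-P, and N-N (M = 18 A) for both
C4'-N-N-C4' and P-N-N-P.  Gating P-N-N-P on the N-N bond is a
documented choice; the alternative P-P gate is isolated behind the same
bin-spec object.  Labeling is direction-symmetric because all three
quadruples are palindromic.

## Potentials

The geometry potential converts per-pair bin probabilities into smooth
curves: `-log((P_b + eps) / (P_ref + eps))` for distances and
`-0.5 log((P_theta_b + eps) / (P_ref + eps))` for dihedrals, splined
over content-bin centers (clamped flat beyond the distance range;
periodic over the circle).  `P_ref` is the final content bin's
probability and acts as the reference state: uniform (uninformative)
restraints produce an identically zero potential and far-apart pairs
feel no spurious force.  Normalizing the dihedral term by its reference
bin keeps uninformative restraints at exactly zero energy, mirroring
the distance term's reference-state treatment; the un-normalized
`-0.5 log(P + eps)` variant is available via
`normalize_dihedral=False`.  `eps` defaults to 1e-4 and is
config-exposed.  The end-to-end potential sums (rather than averages)
the FAPE-form discrepancy against each of the K fixed predictions; the
hybrid energy is their unweighted sum, and either component may be
absent for ablations.

## Folding

The conformation is parameterized per residue by an exponential-map
rotation vector plus a translation (6L unconstrained numbers);
Rodrigues' formula rebuilds rotation matrices inside the autodiff graph
each evaluation, so scipy's L-BFGS-B receives exact gradients.
Defaults: history 10, at most 400 iterations, energy tolerance 1e-6.
One trajectory runs per start — the e2e predictions themselves by
default, or ideal-helix frames with seeded Gaussian noise when only
geometry restraints are given — all under the same consensus potential;
the lowest final energy wins with ties broken by trajectory index, and
NaN trajectories are excluded with a diagnostic.

## Networks at toy scale

The transformer trunk follows the Evoformer pattern (sequence row-wise
gated attention with pair bias, sequence transition 64-128-64, outer
product mean through a 12-d projection, triangle multiplicative updates
with 32 channels, triangle attention with 4 heads of 8, pair
transition), stacked residually with zero-initialized output
projections so a fresh block is the identity.  The structure module
runs 5 iterations of IPA (8 heads, 16 channels, 4 query points, 6 value
points at full scale) from identity frames, composing a
quaternion-derived rotation and translation update per iteration; the
defining equivariance property is asserted numerically.  The two
triangle-attention blocks default to the starting-node and ending-node
orientations; `double_starting_node=True` applies the starting-node
orientation twice instead.  Positional
encodings are a learned index table (1-D) and a relative-position
one-hot clipped at +/-32 (2-D); recycling (3 cycles at full scale)
re-injects layer-normalized previous representations and, in
end-to-end mode, the binned bead-distance map of the previous
structure.

Rotation gradients are *not* detached between structure iterations by
default (`stop_rotation_gradients=False`): at toy scale full gradient
flow is stable and converges several times faster; the detached variant
remains available as the stability device appropriate to large-scale
training.  The toy preset (2 blocks, 16-d representations, 3 structure
iterations, 1 recycle) trains with Adam at the 1e-3 initial learning
rate and overfits a 16-nt hairpin to sub-Angstrom bead RMSD within a
few hundred steps on one CPU.  Full-scale training (48 blocks, weeks of
GPU time) is explicitly out of scope; the toy runs demonstrate
mechanism, not predictive accuracy.

## Oracle fixtures

`OracleConfig` controls how network outputs are emulated from a
reference structure: geometry restraints place a Gaussian over bin
index (circular for dihedrals) centered on the bin measured from a
noise-perturbed copy of the reference (`geometry_noise`, default 1.0 A
P-RMSD — an imperfect-network surrogate; 0 recovers truth-centered
restraints), with width `temperature` (default 0.5 bins; 0 gives
one-hot, large values tend to uniform) and all mass on the extra bin
for out-of-range pairs.  End-to-end replicas compose the true frames
with per-residue noise (rotation angle N(0, 5 deg) about a random axis;
translation N(0, 1 A); K = 6 replicas), emulating an ensemble of
independently trained predictors.  `perturb` rescales Gaussian
coordinate noise until the superposed P-RMSD lands within 10% of its
target.  Under these defaults the desk-scale ablation ordering is
hybrid < e2e-only < geometry-only < unoptimized starts.  These fixtures
establish that the potentials and optimizer recover structures from
restraints of known provenance; they say nothing about the accuracy of
any trained predictor on real RNA, and their error model (independent
Gaussian noise) is far simpler than real network error, which is
correlated along the chain.

## Reconstruction

Full atoms are restored by rigidly superposing each base type's
template nucleotide onto the residue's bead triad (the triad itself is
anchored exactly).  'N' residues are first resolved to U (unpaired) or
the Watson-Crick conjugate of their partner; an N-N pair is an error.
Fast fixes then move non-bead atoms only: O3' is pulled onto the 1.6 A
O3'-P(i+1) bond when outside [1.3, 1.9] A, and non-bonded heavy-atom
pairs closer than 2.0 A are pushed apart with damped 0.4-factor steps,
for at most 40 sweeps; bead atoms are bitwise frozen throughout.  The
external-minimizer hook computes the step count 0.6 * N_atoms / 20 and
shells out to a user-configured command, returning the input unchanged
(with a warning) when none is configured or the tool fails.

## Metrics

TM-score uses the RNA length-dependent d0 (0.6 sqrt(L - 0.5) - 2.5,
with the short-length staircase 0.3/0.4/0.5/0.6/0.7 below L = 30) on
C4' atoms by default, maximized by fragment-seeded Kabsch fits refined
over a shrinking distance-cutoff schedule and finished with a local
6-dof Nelder-Mead polish.  INF is the Matthews correlation coefficient
over the residue-pair universe, per category and pooled, with the
sqrt(PPV*TPR) convention available; DI is RMSD / INF_all.  Handedness
measures, for each base-paired residue with a defined C4' pseudotorsion
over the window (i-1, i, i+1, i+2), whether the model's torsion is
circularly closer to the target's than to the mirrored target's
(negated) torsion; ties count as "not closer".  The clash estimate
counts non-bonded heavy-atom pairs overlapping by at least 0.4 A per
1000 atoms under reduced contact radii (C 1.55, N 1.40, O 1.35,
P 1.80 A) — a deliberately coarse, hydrogen-free surrogate for
MolProbity-style analysis, sized so canonical A-form stacking and
pairing contacts are not flagged.  Watson-Crick pairs are detected
geometrically (complementary bases, purine-N1 to pyrimidine-N3 below
3.5 A, base planes within 60 degrees of parallel, closest-partner
assignment); non-WC and stacking categories are accepted from external
annotations rather than detected.

## Problem sizes

The shipped experiments use a 20-nt hairpin (8-bp stem + 4-nt loop) for
recovery, a 16-nt hairpin for the toy overfit, duplexes of 8-40 nt for
reconstruction, and 6 starts x 10 seeded repeats for the recovery
statistics — sizes chosen so the full suite runs comfortably on a
single CPU while still exercising every code path at realistic
residue counts for these motif types.

## Known limitations

* The A-form builder's loop regions are schematic (finite and
  connective but sterically crowded); only stem geometry is tuned.
* The clash estimate is not MolProbity; numbers are comparable within
  this package only.
* TM-score search is heuristic; it matches a brute-force grid oracle to
  0.005 on the tested instances but carries no global-optimality
  guarantee.
* The oracle error model is independent Gaussian noise; real network
  errors are structured.
* Full-scale training and trained-weight inference are out of scope.
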