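# Methods

## The model in brief

enzgraft implements the four-stage theozyme-grafting protocol for de novo
enzyme design at desk scale. A *theozyme* — a transition-state model plus
disembodied catalytic groups at idealized geometry — is expressed as a
geometric constraint file; a matcher searches scaffold positions where side
chains can realise that geometry; a design stage optimises the surrounding
residue identities under the catalytic restraints; and an evaluation stage
ranks the resulting models. The package is faithful to the *protocol
logic*; the all-atom energetics are a simplified, fully documented stand-in
(see "Energy model" below), so absolute scores are meaningful only within
this package.

## Geometric constraints

A constraint block relates an ordered atom triple on each of two partners
(atom 2 is the base of atom 1, atom 3 the base of atom 2) through six
internal coordinates: distanceAB (atom1–atom1), angle_A, angle_B,
torsion_A, torsion_AB, torsion_B. Each parameter carries ideal value `x0`,
tolerance `xtol`, force constant `k`, a fourth column (covalent flag 0/1
for the distance, periodicity `per` in degrees otherwise) and an optional
sample count `n`.

The penalty is a flat-bottomed periodic harmonic

    p(x) = 0                    if Δ ≤ xtol
    p(x) = k · (Δ − xtol)²      otherwise,

with Δ the minimal absolute deviation of x from any periodic copy
`x0 + m·per` (plain |x − x0| for the distance). This form is zero across
the whole tolerance window (the boundary itself satisfies the restraint),
continuous, and has its minima exactly at the periodic copies — e.g. three
minima per turn for `per = 120`. Atom maps given by type (`atom_type`)
resolve to every matching atom with its two base atoms; the lowest-scoring
triple is used, resolving e.g. the OD1/OD2 ambiguity of a carboxylate.

Angular sample enumeration places `2n+1` equally spaced values across
`[c − xtol, c + xtol]` around every periodic copy `c` in one turn; the
number of ligand placements attempted per rotamer is the product of the six
sample-list lengths.

## Matching

Rotamers come from a reduced library: three canonical samples per rotatable
chi (−60°, 180°, +60°); `ex1`/`ex2` add ±30° satellites about each chi1 /
chi2 value (tripling that chi's samples) and `use_input_sc` appends the
scaffold's own rotamer. Side chains are rebuilt from ideal internal
coordinates off the existing backbone. A full statistical rotamer library
is deliberately out of scope.

*Classic matching* builds, for every rotamer and every sampled parameter
combination, the ligand anchor triple by NeRF placement and rigidly maps
the conformer onto it; placements with any heavy atom closer than
`0.7 · (r_vdw,i + r_vdw,j)` to a backbone atom (N/CA/C/O/CB) are rejected.
*Secondary matching* evaluates candidate rotamers against previously
generated placements, testing only the parameters the block defines
(undefined parameters are ignored); acceptance is exactly equivalent to a
zero flat-bottom penalty. Hits are binned on the 6D pose — origin at the
ligand frame atom 1, frame by Gram–Schmidt over the first block's ligand
triple, z-x-z Euler angles — with default bin widths 1.0 Å and 15°.

Two documented limitations of the plain 6D hash: there is no cross-bin
neighbour merging (hits straddling a boundary do not combine), and near the
Euler degeneracy (second angle ≈ 0 or 180°) bin co-membership does not
imply geometric closeness. The latter is why a match's reported score is
the *realised* restraint sum of the assembled geometry — every rotamer
scored against the shared ligand placement — rather than the sum of the
hits' own scores; matches are ranked by it, and a ground-truth graft scores
exactly 0.

## Energy model

A pairwise heavy-atom model with four terms (weights in parentheses):

* repulsive (1.0): `min(10, (f·σ/d)¹² − 1)` for `d < f·σ`, with
  `σ = r_i + r_j` and onset factor `f = 0.85` (0.75 in soft-repulsive
  design mode). The sub-unity onset reflects that contacts slightly inside
  the nominal vdW sum are routine in well-packed structures;
* attractive (0.8): a shifted `(σ/d)⁶` well truncated at 6 Å, clamped
  below σ;
* hydrogen bond (2.0): a Gaussian in donor–acceptor heavy-atom distance
  centred at 2.9 Å (width 0.3 Å, cutoff 3.6 Å). The weight is chosen so
  that an engineered polar contact outweighs the attractive-term
  differences between rotamers of one side chain;
* per-residue-type reference energies (0–0.5), mildly discouraging large
  or charged residues in design.

Hydrogens are not modelled: polarity (donor/acceptor capability) is a flag
on the heavy atom, and directionality enters through the base-atom angle in
the hydrogen-bond *count* criterion (below). Sequence-adjacent residues
skip backbone–backbone pairs; covalent-flagged constraint pairs and their
1-2/1-3 bonded neighbours are excluded from vdW evaluation.

## Design stage

Residues are labelled by Cα distance to the nearest ligand heavy atom with
cuts cut1 < cut2 < cut3 < cut4 (defaults 6/8/10/12 Å; the 4/6/10/12 Å
variant used for tighter design shells is available through configuration):
within cut1 designable; within cut2 with Cβ closer to that ligand atom than
the Cα, designable; within cut3 repackable; within cut4 with Cβ closer,
repackable; else static. Glycine falls back to the Cα-only test. Catalytic
residues are always repackable (never designed) unless `fix_catalytic_aa`
makes them static. Designable positions may become any amino acid except
cysteine. A resfile (AUTO/NATRO/NATAA/PIKAA/ALLAA) overrides per position;
AUTO defers to the automatic shell.

`cst_opt` mutates the designable/repackable shell to alanine and minimises
the ligand rigid body (plus catalytic chis under `chi_min`, plus movable
backbone under `bb_min`) with a reduced energy — repulsive and restraints
only, no attractive term — and every movable Cα restrained by a 0.5 Å
flat-bottom harmonic. The minimiser is L-BFGS with numerical gradients,
returning the best-visited point, so the objective never increases.
`bb_min` moves backbone atoms in Cartesian space with side chains riding
their Cα shift: an explicit movable-DOF mask replaces fold-tree machinery,
guaranteeing bit-identical static-region coordinates at every stage.

`cst_predock` is Metropolis Monte Carlo on the ligand rigid body:
per-axis Gaussian translations scaled by `trans_magnitude`, Gaussian
rotations scaled by `rot_magnitude` about a random axis through the
centroid of the distance-restrained ligand atoms (so rotations explore
orientation without dragging the restrained contacts), designable residues
as alanine, kT = 1, lowest-energy visited pose returned; fully seeded.

Sequence design runs `design_min_cycles` (default 2) rounds of simulated
annealing packing plus minimisation, restraints on throughout. The packer
precomputes one-body energies (rotamer against static background and
ligand, the ligand term scaled by `lig_packer_weight` = 1.6, reference
energy, a −0.8 native-identity bonus at designable positions, and the
restraint score for catalytic rotamers), prunes to the best 25 rotamers per
position, tabulates two-body side-chain terms for position pairs within
14 Å, and anneals geometrically from kT 10 to 0.05 over 12 stages with
20·N moves per stage, keeping the best assignment.

The final unconstrained repack/minimisation re-optimises the fixed sequence
with restraint weight zero. The ligand rigid body is deliberately *not*
minimised in this stage: without restraints the unbound state is the energy
optimum, and the stage's question is whether the protein holds the
catalytic conformations, which the subsequent metrics (restraint scores,
apo-repack RMSDs) then measure. With the ligand removed entirely
(`final_repack_without_ligand`), per-catalytic-residue side-chain RMSDs
against the liganded model quantify preorganisation.

## Evaluation

Documented geometric criteria (all configurable constants):
hydrogen bond = donor/acceptor heavy atoms of different residues within
3.3 Å with base–donor–acceptor angle ≥ 120°; burial = ≥ 12 heavy-atom
neighbours within 5.2 Å from other residues; buried unsatisfied = buried
polar atom with no hydrogen bond; non-local contact = residue pair with
sequence separation ≥ 6 and any heavy-atom distance ≤ 4.5 Å. The packing
statistic is a proxy: the mean over heavy atoms of neighbour occupancy
`min(1, n/12)`, bounded in [0, 1], reported with the ligand
(`tot_pstat_pm`) and without (`total_nlpstat_pm`); it preserves the
with/without-ligand comparison semantics of a true packing statistic but is
not one. The interface score is the sum of protein–ligand pair terms and
equals total(complex) − total(protein) − total(ligand) exactly, by pairwise
decomposability.

Scorefile columns: per-interaction restraint scores SR1..SRN (cutoffs are
applied per interaction; a residue serving two interactions appears twice)
and the ligand as the last column SR(N+1); `all_cst` is the sum of
SR1..SRN, validated on every record. Default selection cutoffs: all_cst
< 6.5; SR1/SR2/SR3 < 1.2/1.0/2.3; apo-repack RMSDs < 0.5 Å; and, relative
to a repacked reference structure where one is supplied: total score < 0,
buried unsatisfied polars < 5, non-local contacts > −2, packing > −0.05.

## Synthetic study system

The fixtures module generates every input deterministically per seed:

* **Scaffold** — a poly-alanine pocket: two antiparallel ideal-geometry
  helices (Φ/Ψ = −57/−47°) about 13 Å apart over an antiparallel strand
  floor, one chain with numbering gaps at segment junctions
  (unresolved-loop style), ~32 residues. The seed jitters the helix
  separation by ±0.3 Å. An `occluded` variant fills the pocket with
  additional strand layers so no collision-free ligand placement survives —
  the negative control for matching. (A merely *unplanted* pocket is not a
  valid negative: residue identities belong to the matcher, and a
  permissive open pocket can satisfy three interactions by coincidence.)
* **Ligand** — a simplified dihydroxyacetone-phosphate analog with the
  phosphate omitted: C1/C2/C3, carbonyl O1 on C2, hydroxyl O2 on C1.
* **Theozyme** — three interactions in the TIM mechanism's style: a Glu/Asp
  carboxylate base at C1 and a His at the carbonyl O1, both fully specified
  (classic matching, n = 1 per angular parameter; the torsion about the
  hydrogen bond gets k = 0 and a wide tolerance), and a Lys at the hydroxyl
  O2 constraining only distance, both angles and torsion_A (secondary
  matching). The numeric geometries are chemically sensible hydrogen-bond
  values chosen once for this fixture; they are not measurements of any
  real enzyme.
* **Planted sites** — inverse construction: a library rotamer at a pocket
  position places the ligand at the first block's ideal values; for each
  further block a residue built with library chi angles is rigidly moved so
  its constrained triple realises the block's ideal values exactly
  (undefined torsions swept on a 30° grid; the candidate with the smallest
  Cα displacement ≤ 3.5 Å that keeps the ligand clash-free wins), carrying
  its backbone with it. Every defined parameter therefore measures exactly
  x0 at the truth, the truth chi angles are exact library values, and the
  matcher must recover the graft.

What passing tests on these fixtures do **not** show: performance on real
scaffolds (no loops, no crystallographic imperfections, no solvent), real
rotamer statistics, or real energetics — match counts and design statistics
from any published study are out of reach by construction and are not
reproduced here.

## Numerical choices and problem sizes

Degenerate geometry (collinearity) is flagged below sin θ = 1e-8; torsions
live in [−180, 180), Euler angles in [0, 360); periodic copies deduplicate
at 1e-6°; ties in the matcher break by restraint score then position index,
making output ordering deterministic. The clash test runs in float32 (≈
0.01 Å distance precision, far below the 0.7-factor margin). All
stochastic stages (predock, packing, fixture generation) consume explicit
integer seeds.

Test-suite problem sizes: 10⁴ random tuples for the build/measure round
trip; 25 planted pockets plus 25 occluded negatives for matcher recovery
(~3–4 minutes, one CPU); 100 random structures against the brute-force
shell oracle; design-stage contracts on a single planted match. Fixture
sampling counts (n = 1 on angular parameters) keep one matcher run at a
few seconds while still exercising multi-sample enumeration.

## Known limitations

* The energy model is a toy: no solvation, no electrostatics beyond the
  hydrogen-bond Gaussian, no torsional strain; design sequences on the open
  fixture pocket therefore over-favour large residues, and the final
  unconstrained repack frequently releases the catalytic geometry — which
  the preorganisation metrics are designed to expose, but which limits how
  "good" a toy design can look.
* Proline's ring closure is not enforced (two-chi approximation); backbone
  minimisation is Cartesian with a Cα restraint rather than torsional.
* The 6D hash has no neighbour merging and inherits the Euler degeneracy
  discussed above.
* Secondary matching of side-chain–side-chain blocks is implemented but
  only lightly exercised by the fixtures (the TIM-style theozyme is fully
  ligand-mediated).
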