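# enzgraft

Desk-scale de novo enzyme design: graft a minimal catalytic-site model (a
*theozyme*) into protein scaffolds and design the surrounding shell to hold
it.

Computational enzyme design asks whether an inert protein scaffold can be
turned into a catalyst for a chosen reaction. The protocol implemented here
takes the classic four-stage route, using the triosephosphate-isomerase
(TIM) reaction — the isomerization of dihydroxyacetone phosphate — as its
worked system:

1. **Theozyme as geometry.** The catalytic idea (here: a Glu/Asp base
   abstracting a proton from substrate C1, a His polarizing the carbonyl,
   a Lys stabilizing the developing alkoxide) is written as a *constraint
   file*: one block per catalytic interaction, each relating an atom triple
   on the ligand to an atom triple on the residue through six internal
   coordinates — distanceAB, angle_A, angle_B, torsion_A, torsion_AB,
   torsion_B. Each parameter carries an ideal value x0, tolerance xtol,
   force constant k, a periodicity (or covalent flag for the distance), and
   a sample count n. Violations are scored with a flat-bottomed periodic
   harmonic: p(x) = 0 for |Δ| ≤ xtol, k·(|Δ| − xtol)² beyond, where Δ is
   the deviation from the nearest periodic copy of x0.
2. **Matching.** *Classic matching* builds side-chain rotamers at candidate
   scaffold positions and, for each rotamer, places the ligand at every
   combination of the 2n+1 sampled parameter values; collision-free
   placements ("hits") are hashed on a 6D pose (3 Euclidean + 3 Euler
   coordinates). *Secondary matching* instead re-evaluates rotamers against
   previously generated placements, checking only the parameters the block
   defines. A 6D bin holding hits from all N interactions is a **match** —
   a successful graft.
3. **Design.** Around each match, residues are split into designable /
   repackable / static shells by Cα distance cuts from the ligand
   (6/8/10/12 Å defaults). The catalytic geometry is first optimized with
   the shell as alanine (cst_opt), then sequence design and minimisation
   alternate under the restraints, with protein–ligand interactions
   upweighted 1.6× and a 0.8-unit bonus for keeping the native identity.
   A final repack runs without restraints.
4. **Evaluation.** Each model is scored: total energy (restraints
   excluded), restraint score in total and per catalytic residue
   (SR1..SRN; the ligand is SR(N+1)), protein–ligand interface score,
   packing proxies with/without ligand, buried unsatisfied polar atoms,
   non-local contacts, hydrogen bonds, and apo-repack RMSDs
   (preorganisation). Designs are selected by metric cutoffs.

Everything runs on synthetic inputs generated by `enzgraft.fixtures`: a toy
two-helix pocket scaffold, a simplified DHAP-like ligand, a TIM-style
three-interaction theozyme, and *planted sites* with exact ground truth, so
the whole pipeline is testable on one CPU with no downloads. The energy
model is a small documented stand-in (repulsive + attractive + hydrogen
bond + reference energies), not the full biomolecular force field its role
imitates; absolute energies are not comparable across packages. See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

```bash
python examples/01_theozyme_cstfile.py
```

```
ligand: 1n1; catalytic partner may be any of GLU, ASP (carboxylate-O by type)
  distanceAB  x0=3.06     n=0  -> 1 samples: 3.06
  angle_A     x0=73.6     n=1  -> 3 samples: 63.6, 73.6, 83.6
  angle_B     x0=120      n=1  -> 3 samples: 105, 120, 135
  torsion_A   x0=-101.2   n=1  -> 3 samples: 243.8, 258.8, 273.8
  torsion_AB  x0=180      n=3  -> 7 samples: 90, 120, 150, 180, 210, 240, 270
  torsion_B   x0=180      n=1  -> 3 samples: 165, 180, 195
ligand placements attempted per rotamer: 567
```

The matcher samples three values (63.6, 73.6, 83.6°) for an angle with
x0 = 73.6, xtol = 10 and n = 1, and attempts 1·3·3·3·7·3 = 567 ligand
placements per rotamer for this block. `examples/02_matching.py` grafts the
three-residue theozyme into a planted toy pocket and recovers the ground
truth:

```
hits per interaction: 37083, 5284, 4784
occupied 6D bins: 33797; matches: 3
ground-truth match recovered: True
best match score (realised restraint sum): 0.000
```

`examples/03_design.py` designs the shell around that match and prints the
restraint score per stage (low while restraints are on; the jump at the
unconstrained repack shows this open toy pocket does not hold the site by
itself — exactly what the preorganisation metrics are for), and
`examples/04_scoring.py` writes a scorefile and applies selection cutoffs.

The same stages are available as a CLI for shell use:

```bash
enzgraft fixture --seed 4 -out_dir work
enzgraft match -s work/scaffold.pdb -extra_res_fa work/ligand.params \
    -geometric_constraint_file work/theozyme.cst \
    -scaffold_active_site_residues work/positions.pos -secondary 3
enzgraft design -s matches/match_0001.pdb ... -o design.pdb
enzgraft score -s design.pdb ... -o scores.sc
```

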