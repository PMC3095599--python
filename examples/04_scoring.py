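"""Score models, write a scorefile, and select designs by cutoffs.

Each model is summarised by a metric vector: total energy (restraints
excluded), restraint score per catalytic residue (SR1..SRN; the ligand is
the last SR), protein-ligand interface score, packing proxies with and
without the ligand, buried unsatisfied polar atoms, non-local contacts and
hydrogen-bond counts.  Designs pass when every cutoff holds.
"""

from enzgraft import fixtures
from enzgraft.design import DesignConfig
from enzgraft.evaluate import (compute_score_record, filter_designs,
                               parse_cutoffs, write_scorefile)
from enzgraft.matcher import match_structure, run_matcher

scaffold = fixtures.make_toy_scaffold(seed=1)
site = fixtures.plant_site(scaffold, seed=1)
matches, _ = run_matcher(site.scaffold, site.theozyme, site.positions,
                         site.ligand)

records = []
for i, m in enumerate(matches[:3], start=1):
    st = match_structure(m, site.scaffold, site.ligand)
    records.append(compute_score_record(st, site.theozyme, site.ligand,
                                        design_id=f"match_{i}",
                                        cfg=DesignConfig(seed=i)))
write_scorefile(records, "scores.sc")
print(f"{len(records)} records written to scores.sc")
print("columns:", ", ".join(list(records[0].metrics)[:8]), "...")

cutoffs = parse_cutoffs("""
all_cst < 6.5
SR1 < 1.2
SR2 < 1.0
SR3 < 2.3
active_site_rmsd < 0.5
""")
passing, counts = filter_designs(records, cutoffs)
for name, n in counts.items():
    print(f"  {name}: {n}/{len(records)} pass")
print(f"models passing all cutoffs: {len(passing)} "
      f"({', '.join(r.design_id for r in passing) or 'none'})")
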