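"""A simplified, pairwise-decomposable energy model for packing and design.

This is a deliberately small, fully documented model — four closed-form
terms, not a production all-atom force field: a repulsive term that keeps
atoms apart, a short-range attractive term that rewards packing, a
distance-based polar (hydrogen-bond) term, and per-residue-type reference
energies.  Absolute values are meaningful only within this package; the
protocol logic built on top of it (which terms are active in which stage,
how the ligand interaction is weighted) is what carries over to real
design engines.

Closed forms, for heavy atoms i, j with vdW radii r_i, r_j at distance d,
sigma = r_i + r_j:

    repulsive   w_rep * min(cap, (f*sigma/d)^12 - 1)        for d < f*sigma,
                f = 0.85 (hard) or 0.75 (soft) — contacts slightly inside
                the nominal vdW sum are common in well-packed proteins
    attractive  -w_atr * ((sigma/d)^6 - (sigma/6.0)^6)       for sigma <= d <= 6 A
                (clamped to its value at d = sigma for d < sigma)
    hbond       -w_hb * exp(-(d - 2.9)^2 / (2 * 0.3^2))      donor/acceptor pairs,
                                                             d <= 3.6 A
    reference   per-residue-type constant, added once per designable residue

``soft`` mode uses the smaller repulsive onset (the soft-repulsive design
variant).  Interactions between residues adjacent in sequence skip
backbone-backbone atom pairs (they are covalently linked); explicitly
declared covalent constraint pairs and their 1-2/1-3 bonded neighbours are
excluded from repulsive/attractive evaluation via an exclusion set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Residue, Structure

ATR_CUTOFF = 6.0
REP_FACTOR_HARD = 0.85
REP_FACTOR_SOFT = 0.75
HB_CUTOFF = 3.6
HB_IDEAL = 2.9
HB_WIDTH = 0.3

# small biases discouraging over-use of large/charged residues in design
REFERENCE_ENERGIES = {
    "ALA": 0.0, "GLY": 0.2, "SER": 0.1, "THR": 0.1, "VAL": 0.0,
    "LEU": 0.1, "ILE": 0.1, "MET": 0.3, "PHE": 0.3, "TYR": 0.3,
    "TRP": 0.5, "ASP": 0.2, "GLU": 0.3, "ASN": 0.2, "GLN": 0.3,
    "HIS": 0.3, "LYS": 0.4, "ARG": 0.5, "PRO": 0.3, "CYS": 0.2,
}


@dataclass
class EnergyModel:
    """Weights of the simplified energy; all non-negative."""

    w_rep: float = 1.0
    w_atr: float = 0.8
    w_hb: float = 2.0
    w_cst: float = 1.0
    rep_cap: float = 10.0
    soft: bool = False
    reference: dict = field(default_factory=lambda: dict(REFERENCE_ENERGIES))

    def __post_init__(self):
        for name in ("w_rep", "w_atr", "w_hb", "w_cst"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- atom-array pair terms ------------------------------------------------

    def pair_terms(self, xyz_a, rad_a, pol_a, xyz_b, rad_b, pol_b,
                   exclude_mask=None) -> dict:
        """Summed pair energies between two atom sets.

        ``pol_*`` are (n, 2) boolean arrays (donor, acceptor) per atom.
        ``exclude_mask`` (n_a, n_b) removes pairs from rep/atr evaluation.
        Returns {'rep', 'atr', 'hb'} totals.
        """
        xyz_a = np.atleast_2d(xyz_a)
        xyz_b = np.atleast_2d(xyz_b)
        diff = xyz_a[:, None, :] - xyz_b[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        d = np.maximum(d, 1e-6)
        sigma = rad_a[:, None] + rad_b[None, :]
        if exclude_mask is not None:
            active = ~exclude_mask
        else:
            active = np.ones_like(d, bool)

        rep_sigma = sigma * (REP_FACTOR_SOFT if self.soft
                             else REP_FACTOR_HARD)
        inside = (d < rep_sigma) & active
        rep = np.zeros_like(d)
        with np.errstate(over="ignore"):
            rep[inside] = np.minimum(
                self.rep_cap, (rep_sigma[inside] / d[inside]) ** 12 - 1.0)
        rep_total = self.w_rep * float(np.sum(rep))

        shift = (sigma / ATR_CUTOFF) ** 6
        atr = np.zeros_like(d)
        in_well = (d >= sigma) & (d <= ATR_CUTOFF) & active
        atr[in_well] = (sigma[in_well] / d[in_well]) ** 6 - shift[in_well]
        clamped = (d < sigma) & active
        atr[clamped] = 1.0 - shift[clamped]
        atr_total = -self.w_atr * float(np.sum(atr))

        hb_pair = ((pol_a[:, None, 0] & pol_b[None, :, 1])
                   | (pol_a[:, None, 1] & pol_b[None, :, 0]))
        hb_sel = hb_pair & (d <= HB_CUTOFF)
        hb = np.exp(-((d[hb_sel] - HB_IDEAL) ** 2) / (2.0 * HB_WIDTH ** 2))
        hb_total = -self.w_hb * float(np.sum(hb))
        return {"rep": rep_total, "atr": atr_total, "hb": hb_total}

    # -- residue-level wrappers ----------------------------------------------

    @staticmethod
    def _arrays(res) -> tuple:
        """(xyz, radii, polarity) arrays for a Residue or coords/atoms pair."""
        atoms = list(res.atoms.values())
        xyz = np.stack([a.xyz for a in atoms])
        rad = np.array([a.radius for a in atoms])
        pol = np.array([[a.donor, a.acceptor] for a in atoms], bool)
        return xyz, rad, pol

    @staticmethod
    def _adjacent(res_a: Residue, res_b: Residue) -> bool:
        return (res_a.chain == res_b.chain
                and abs(res_a.number - res_b.number) == 1)

    def residue_pair_energy(self, res_a: Residue, res_b: Residue,
                            exclusions: set = frozenset()) -> dict:
        """Pair terms between two residues (or residue and ligand copy).

        ``exclusions`` holds frozensets of ((chain, number, atom), ...) pairs
        whose rep/atr evaluation is skipped (covalent constraint semantics).
        """
        xyz_a, rad_a, pol_a = self._arrays(res_a)
        xyz_b, rad_b, pol_b = self._arrays(res_b)
        names_a = list(res_a.atoms)
        names_b = list(res_b.atoms)
        mask = np.zeros((len(names_a), len(names_b)), bool)
        if self._adjacent(res_a, res_b):
            bb_a = np.array([res_a.atoms[n].backbone for n in names_a])
            bb_b = np.array([res_b.atoms[n].backbone for n in names_b])
            mask |= bb_a[:, None] & bb_b[None, :]
        if exclusions:
            for i, na in enumerate(names_a):
                ka = (res_a.chain, res_a.number, na)
                for j, nb in enumerate(names_b):
                    if frozenset((ka, (res_b.chain, res_b.number, nb))) \
                            in exclusions:
                        mask[i, j] = True
        return self.pair_terms(xyz_a, rad_a, pol_a, xyz_b, rad_b, pol_b, mask)

    def structure_energy(self, structure: Structure, lig_weight: float = 1.0,
                         exclusions: set = frozenset(),
                         include_reference: bool = True) -> dict:
        """Total energy breakdown of a structure (restraints not included).

        Protein-ligand pair terms are multiplied by ``lig_weight``.  Pairs
        beyond 8 A centroid distance are skipped (all terms vanish there).
        Returns {'total', 'rep', 'atr', 'hb', 'ref', 'lig_rep', 'lig_atr',
        'lig_hb'}.
        """
        units = list(structure.residues) + list(structure.ligands)
        cents = np.stack([u.heavy_coords().mean(axis=0) for u in units])
        spans = np.array([
            np.max(np.linalg.norm(u.heavy_coords() - c, axis=1))
            for u, c in zip(units, cents)])
        out = {"rep": 0.0, "atr": 0.0, "hb": 0.0,
               "lig_rep": 0.0, "lig_atr": 0.0, "lig_hb": 0.0}
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                reach = spans[i] + spans[j] + ATR_CUTOFF
                if np.linalg.norm(cents[i] - cents[j]) > reach:
                    continue
                terms = self.residue_pair_energy(units[i], units[j],
                                                 exclusions)
                is_lig = units[i].is_ligand != units[j].is_ligand
                w = lig_weight if is_lig else 1.0
                for k in ("rep", "atr", "hb"):
                    out[k] += w * terms[k]
                    if is_lig:
                        out[f"lig_{k}"] += terms[k]
        out["ref"] = (sum(self.reference.get(r.name3, 0.0)
                          for r in structure.residues)
                      if include_reference else 0.0)
        out["total"] = out["rep"] + out["atr"] + out["hb"] + out["ref"]
        return out


def covalent_exclusions(structure: Structure, theozyme, ligand_topology) -> set:
    """Atom-pair exclusions implied by covalent-flagged distance constraints.

    For each block whose distanceAB is covalent, the constrained atom pair
    and their 1-2/1-3 bonded neighbours skip vdW evaluation.
    """
    from .cst import resolve_atom_triples
    from .chem import RESIDUE_TOPOLOGIES

    out: set = set()
    cat = {i: res for i, res in structure.catalytic_residues()}
    if not structure.ligands:
        return out
    lig = structure.ligand
    for bi, block in enumerate(theozyme.blocks, start=1):
        p = block.params.get("distanceAB")
        if p is None or not p.is_covalent or bi not in cat:
            continue
        res = cat[bi]
        topo = RESIDUE_TOPOLOGIES[res.name3]
        lig_names = resolve_atom_triples(block.ligand_map, ligand_topology)
        prot_names = resolve_atom_triples(block.protein_map, topo)

        def protein_neighbors(atom: str) -> set:
            # 1-2 and 1-3 neighbours along the side-chain tree (both ways)
            near = {atom}
            parent = topo.parent_of(atom)
            if parent:
                near.add(parent)
                gp = topo.parent_of(parent)
                if gp:
                    near.add(gp)
            for other in res.atoms:
                try:
                    p1 = topo.parent_of(other)
                except KeyError:
                    continue
                if p1 == atom:
                    near.add(other)
                elif p1 and topo.parent_of(p1) == atom:
                    near.add(other)
            return near

        for lt in lig_names:
            lig_set = ({lt[0]} | ligand_topology.bonded_neighbors(lt[0], 2))
            for pt in prot_names:
                prot_set = protein_neighbors(pt[0])
                for a in lig_set:
                    for b in prot_set:
                        out.add(frozenset((
                            (lig.chain, lig.number, a),
                            (res.chain, res.number, b))))
    return out
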