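"""Structures, ligand topologies, and the text formats that carry them.

PDB coordinate records are read and written through gemmi.  Catalytic
annotations ride along as remark lines in a single documented dialect::

    REMARK 999 CATALYTIC <block#> <chain> <resnum> <restype>

one line per theozyme interaction, naming the protein residue that realises
it.  The ligand params dialect (ATOM/BOND/ICOOR records plus optional stored
conformers) describes a small molecule as an internal-coordinate tree so that
its geometry can be rebuilt and rigidly re-placed; the posfile is a list of
scaffold residue numbers eligible for matching.

Internally residue and atom collections are 0-based; PDB residue numbering
(1-based, per chain) appears only at this reader/writer boundary.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import geometry
from .chem import (BACKBONE_ACCEPTOR, BACKBONE_DONOR, BACKBONE_GEOMETRY,
                   RESIDUE_TOPOLOGIES, VDW_RADII)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    """One heavy atom: name, element, coordinates and derived properties."""

    name: str
    element: str
    xyz: np.ndarray
    radius: float = 0.0
    donor: bool = False
    acceptor: bool = False
    backbone: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, float)
        if self.radius <= 0.0:
            self.radius = VDW_RADII.get(self.element.upper(), 1.7)


@dataclass
class Residue:
    """A protein residue or a placed ligand copy (``is_ligand`` True)."""

    name3: str
    chain: str
    number: int
    atoms: dict = field(default_factory=dict)   # name -> Atom, insertion-ordered
    is_ligand: bool = False

    def coord(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name].xyz
        except KeyError:
            raise StructureError(
                f"{self.name3} {self.chain}{self.number} has no atom {name!r}"
            ) from None

    def has(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)

    def coords_dict(self) -> dict:
        return {n: a.xyz for n, a in self.atoms.items()}

    def heavy_coords(self) -> np.ndarray:
        return np.stack([a.xyz for a in self.atoms.values()])

    @property
    def topology(self):
        return RESIDUE_TOPOLOGIES[self.name3]

    @property
    def key(self):
        return (self.chain, self.number)

    def copy(self) -> "Residue":
        return _copy.deepcopy(self)


@dataclass
class CatalyticAnnotation:
    block_index: int      # 1-based theozyme interaction index
    chain: str
    number: int
    name3: str


@dataclass
class Structure:
    """Ordered protein residues plus ligand copies and catalytic annotations."""

    residues: list = field(default_factory=list)
    ligands: list = field(default_factory=list)
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self._index = {r.key: r for r in self.residues}

    def reindex(self) -> None:
        self._index = {r.key: r for r in self.residues}

    def find(self, chain: str, number: int) -> Residue:
        try:
            return self._index[(chain, number)]
        except KeyError:
            raise StructureError(f"no residue {chain}{number} in structure") from None

    @property
    def ligand(self) -> Residue:
        if not self.ligands:
            raise StructureError("structure has no ligand")
        return self.ligands[0]

    def catalytic_residues(self) -> list:
        """(block_index, Residue) pairs in block order; validates references."""
        out = []
        for ann in sorted(self.annotations, key=lambda a: a.block_index):
            res = self.find(ann.chain, ann.number)
            if res.name3 != ann.name3:
                raise StructureError(
                    f"catalytic annotation {ann} names {ann.name3} but residue is "
                    f"{res.name3}")
            out.append((ann.block_index, res))
        return out

    def catalytic_keys(self) -> set:
        return {(a.chain, a.number) for a in self.annotations}

    def copy(self) -> "Structure":
        st = Structure(
            residues=[r.copy() for r in self.residues],
            ligands=[l.copy() for l in self.ligands],
            annotations=[_copy.deepcopy(a) for a in self.annotations],
        )
        return st

    def all_atoms(self, include_ligand: bool = True):
        for res in self.residues:
            for a in res.atoms.values():
                yield res, a
        if include_ligand:
            for lig in self.ligands:
                for a in lig.atoms.values():
                    yield lig, a


# ---------------------------------------------------------------------------
# side-chain construction
# ---------------------------------------------------------------------------

def annotate_protein_atom(res_name3: str, atom: Atom) -> None:
    """Fill donor/acceptor/backbone flags from the residue topology."""
    if atom.name in BACKBONE_ATOMS or atom.name == "CB":
        atom.backbone = True
        atom.donor = atom.name in BACKBONE_DONOR and res_name3 != "PRO"
        atom.acceptor = atom.name in BACKBONE_ACCEPTOR
        return
    topo = RESIDUE_TOPOLOGIES.get(res_name3)
    if topo is None:
        return
    for sc in topo.side_chain:
        if sc.name == atom.name:
            atom.donor = sc.donor
            atom.acceptor = sc.acceptor
            return


def build_side_chain_batch(residue: Residue, name3: str,
                           chi_sets: np.ndarray) -> dict:
    """Side-chain coordinates for many chi combinations at once.

    ``chi_sets`` has shape (C, n_chi).  Returns atom name -> array: (3,) for
    backbone/CB atoms (shared) and (C, 3) for chi-dependent atoms.
    """
    topo = RESIDUE_TOPOLOGIES[name3]
    chi_sets = np.atleast_2d(np.asarray(chi_sets, float))
    if chi_sets.shape[1] != topo.n_chi:
        raise StructureError(
            f"{name3} needs {topo.n_chi} chi angles, got {chi_sets.shape[1]}")
    coords: dict = {bb: np.asarray(residue.coord(bb), float)
                    for bb in BACKBONE_ATOMS}
    if topo.has_cb:
        coords["CB"] = geometry.place_atom(
            coords["C"], coords["N"], coords["CA"],
            BACKBONE_GEOMETRY["CA_CB"], BACKBONE_GEOMETRY["N_CA_CB"],
            BACKBONE_GEOMETRY["CB_IMPROPER"])
    for sc in topo.side_chain:
        kind, arg, offset = sc.torsion
        phi = chi_sets[:, arg - 1] + offset if kind == "chi" else arg
        coords[sc.name] = geometry.place_atom(
            coords[sc.ref3], coords[sc.ref2], coords[sc.parent],
            sc.bond, sc.angle, phi)
    return coords


def residue_from_coords(template: Residue, name3: str, coords: dict) -> Residue:
    """A Residue of type ``name3`` at the template's chain/number."""
    topo = RESIDUE_TOPOLOGIES[name3]
    out = Residue(name3=name3, chain=template.chain, number=template.number)
    for bb in BACKBONE_ATOMS:
        out.atoms[bb] = Atom(bb, "N" if bb == "N" else ("O" if bb == "O" else "C"),
                             coords[bb])
    if topo.has_cb:
        out.atoms["CB"] = Atom("CB", "C", coords["CB"])
    for sc in topo.side_chain:
        out.atoms[sc.name] = Atom(sc.name, sc.element, coords[sc.name])
    for a in out.atoms.values():
        annotate_protein_atom(name3, a)
    return out


def build_side_chain(residue: Residue, name3: str, chis) -> Residue:
    """Rebuild ``residue`` as type ``name3`` with the given chi angles.

    Backbone N/CA/C/O coordinates are kept; CB and all side-chain atoms are
    constructed from ideal internal coordinates.  Returns a new Residue.
    """
    batch = build_side_chain_batch(
        residue, name3, np.asarray(list(chis), float).reshape(1, -1))
    coords = {n: (v[0] if v.ndim == 2 else v) for n, v in batch.items()}
    return residue_from_coords(residue, name3, coords)


def measure_chis(residue: Residue) -> list:
    """Chi angles of a residue measured from its coordinates (degrees)."""
    topo = residue.topology
    out = []
    for quad in topo.chi_atoms:
        out.append(float(geometry.dihedral(*(residue.coord(n) for n in quad))))
    return out


def side_chain_rmsd(res_a: Residue, res_b: Residue) -> float:
    """Heavy-atom RMSD over shared non-backbone atoms (no superposition)."""
    names = [n for n in res_a.atoms
             if n not in BACKBONE_ATOMS and n in res_b.atoms]
    if not names:
        return 0.0
    d = np.stack([res_a.coord(n) - res_b.coord(n) for n in names])
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# ligand topology
# ---------------------------------------------------------------------------

@dataclass
class LigandAtom:
    name: str
    element: str
    atom_type: str
    donor: bool = False
    acceptor: bool = False

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), 1.7)


@dataclass
class IcoorRecord:
    name: str
    d: float
    theta: float
    phi: float
    parent: str
    ref2: str
    ref3: str


@dataclass
class LigandTopology:
    """A small-molecule ligand: typed atoms, bonds, internal-coordinate tree.

    The tree is rooted at the first atom; each later atom is placed from
    three previously defined atoms.  Conformer 0 is rebuilt from the tree;
    further stored conformers may override torsions.
    """

    name3: str
    atoms: list = field(default_factory=list)      # LigandAtom, ordered
    bonds: list = field(default_factory=list)      # (name, name)
    icoor: list = field(default_factory=list)      # IcoorRecord, tree order
    conformers: list = field(default_factory=list)  # list[dict name -> xyz]

    def __post_init__(self):
        self._by_name = {a.name: a for a in self.atoms}
        if not self.conformers and self.icoor:
            self.conformers = [self.rebuild_conformer()]

    # --- topology protocol shared with ResidueTopology ---
    def atom_names(self) -> list:
        return [a.name for a in self.atoms]

    def atom(self, name: str) -> LigandAtom:
        return self._by_name[name]

    def parent_of(self, name: str) -> str | None:
        for rec in self.icoor:
            if rec.name == name:
                return rec.parent if rec.parent != name else None
        raise KeyError(f"ligand {self.name3} has no atom {name!r}")

    def atoms_of_type(self, type_symbol: str) -> list:
        return [a.name for a in self.atoms if a.atom_type == type_symbol]

    # --- geometry ---
    def rebuild_conformer(self) -> dict:
        """Coordinates built from the internal-coordinate tree.

        The root atom sits at the origin, its first child along +x, the
        second child in the xy-plane; later atoms are NeRF placements.
        """
        coords: dict = {}
        for i, rec in enumerate(self.icoor):
            if i > 0:
                for ref in {rec.parent, rec.ref2, rec.ref3} if i > 2 \
                        else {rec.parent} if i == 1 else {rec.parent, rec.ref2}:
                    if ref not in coords:
                        raise StructureError(
                            f"icoor for {rec.name} references undefined atom "
                            f"{ref!r}")
            if i == 0:
                coords[rec.name] = np.zeros(3)
            elif i == 1:
                coords[rec.name] = coords[rec.parent] + np.array([rec.d, 0.0, 0.0])
            elif i == 2:
                p = coords[rec.parent]
                r2 = coords[rec.ref2]
                direction = (r2 - p) / np.linalg.norm(r2 - p)
                th = np.radians(rec.theta)
                # in-plane placement at the stated angle from the ref2 arm
                perp = np.array([-direction[1], direction[0], 0.0])
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                coords[rec.name] = p + rec.d * (np.cos(th) * direction
                                                + np.sin(th) * perp)
            else:
                for ref in (rec.parent, rec.ref2, rec.ref3):
                    if ref not in coords:
                        raise StructureError(
                            f"icoor for {rec.name} references undefined atom {ref!r}")
                coords[rec.name] = geometry.place_atom(
                    coords[rec.ref3], coords[rec.ref2], coords[rec.parent],
                    rec.d, rec.theta, rec.phi)
        missing = [a.name for a in self.atoms if a.name not in coords]
        if missing:
            raise StructureError(
                f"icoor tree does not span atoms: {', '.join(missing)}")
        return coords

    def validate(self) -> None:
        if not self.atoms:
            raise StructureError("ligand topology has no atoms")
        names = set(self.atom_names())
        if len(names) != len(self.atoms):
            raise StructureError("duplicate atom names in ligand topology")
        for a, b in self.bonds:
            if a not in names or b not in names:
                raise StructureError(f"bond {a}-{b} references undeclared atom")
        seen: set = set()
        for i, rec in enumerate(self.icoor):
            if rec.name not in names:
                raise StructureError(f"icoor names undeclared atom {rec.name!r}")
            refs = [rec.parent, rec.ref2, rec.ref3][: min(i, 3)]
            for ref in refs:
                if ref not in seen:
                    raise StructureError(
                        f"icoor for {rec.name} references {ref!r} before definition")
            seen.add(rec.name)
        if seen != names:
            raise StructureError("icoor tree does not span all atoms")
        rebuilt = self.rebuild_conformer()
        stored = self.conformers[0]
        err = max(np.linalg.norm(rebuilt[n] - np.asarray(stored[n], float))
                  for n in names)
        if err > 1e-4:
            raise StructureError(
                f"stored conformer deviates {err:.2e} A from icoor rebuild")

    def bonded_neighbors(self, name: str, depth: int = 1) -> set:
        """Atoms within ``depth`` bonds of ``name`` (excluding itself)."""
        adj: dict = {a.name: set() for a in self.atoms}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        frontier = {name}
        seen = {name}
        for _ in range(depth):
            frontier = {n for f in frontier for n in adj[f]} - seen
            seen |= frontier
        return seen - {name}

    def internal_bond(self, a: str, b: str) -> float:
        c = self.conformers[0]
        return float(np.linalg.norm(np.asarray(c[a]) - np.asarray(c[b])))

    def internal_angle(self, a: str, b: str, c: str) -> float:
        cf = self.conformers[0]
        return float(geometry.angle(cf[a], cf[b], cf[c]))

    def placed_residue(self, coords: dict, chain: str = "X",
                       number: int = 1) -> Residue:
        res = Residue(name3=self.name3, chain=chain, number=number,
                      is_ligand=True)
        for a in self.atoms:
            res.atoms[a.name] = Atom(a.name, a.element,
                                     np.asarray(coords[a.name], float),
                                     donor=a.donor, acceptor=a.acceptor)
        return res


# ---------------------------------------------------------------------------
# params dialect
# ---------------------------------------------------------------------------

def parse_ligand_params(text) -> LigandTopology:
    """Parse the ligand params dialect (NAME/ATOM/BOND/ICOOR/CONF records)."""
    if hasattr(text, "read"):
        text = text.read()
    name3 = ""
    atoms: list = []
    bonds: list = []
    icoor: list = []
    conformers: list = []
    current_conf: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        rec = tok[0].upper()
        try:
            if rec == "NAME":
                name3 = tok[1]
            elif rec == "ATOM":
                flags = [t.upper() for t in tok[4:]]
                atoms.append(LigandAtom(
                    name=tok[1], element=tok[2], atom_type=tok[3],
                    donor="DONOR" in flags, acceptor="ACCEPTOR" in flags))
            elif rec == "BOND":
                bonds.append((tok[1], tok[2]))
            elif rec == "ICOOR":
                icoor.append(IcoorRecord(
                    name=tok[1], d=float(tok[2]), theta=float(tok[3]),
                    phi=float(tok[4]), parent=tok[5], ref2=tok[6], ref3=tok[7]))
            elif rec == "CONF":
                current_conf = {}
                conformers.append(current_conf)
            elif rec == "XYZ":
                if current_conf is None:
                    raise StructureError("XYZ record outside CONF block")
                current_conf[tok[1]] = np.array(
                    [float(tok[2]), float(tok[3]), float(tok[4])])
            else:
                raise StructureError(f"unknown params record {rec!r}")
        except (IndexError, ValueError) as exc:
            raise StructureError(f"params line {lineno}: {exc}") from None
    topo = LigandTopology(name3=name3, atoms=atoms, bonds=bonds, icoor=icoor,
                          conformers=conformers)
    topo.validate()
    return topo


def write_ligand_params(topo: LigandTopology) -> str:
    out = [f"NAME {topo.name3}"]
    for a in topo.atoms:
        flags = (" DONOR" if a.donor else "") + (" ACCEPTOR" if a.acceptor else "")
        out.append(f"ATOM {a.name} {a.element} {a.atom_type}{flags}")
    for a, b in topo.bonds:
        out.append(f"BOND {a} {b}")
    for rec in topo.icoor:
        out.append(f"ICOOR {rec.name} {rec.d:.6f} {rec.theta:.6f} {rec.phi:.6f} "
                   f"{rec.parent} {rec.ref2} {rec.ref3}")
    for conf in topo.conformers:
        out.append("CONF")
        for name, xyz in conf.items():
            out.append(f"XYZ {name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# posfile
# ---------------------------------------------------------------------------

def parse_posfile(text) -> list:
    """Residue selectors from a posfile: numbers, optionally chain-prefixed.

    '10 14 A22' -> [(None, 10), (None, 14), ('A', 22)], ordered, deduplicated.
    """
    if hasattr(text, "read"):
        text = text.read()
    out: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        for tok in line.split():
            chain = None
            body = tok
            if body and body[0].isalpha():
                chain, body = body[0], body[1:]
            try:
                num = int(body)
            except ValueError:
                raise StructureError(
                    f"posfile line {lineno}: non-numeric token {tok!r}") from None
            sel = (chain, num)
            if sel not in out:
                out.append(sel)
    return out


# ---------------------------------------------------------------------------
# PDB io
# ---------------------------------------------------------------------------

_CATALYTIC_PREFIX = ("REMARK", "999", "CATALYTIC")


def _parse_catalytic_remarks(lines) -> list:
    out = []
    for lineno, line in enumerate(lines, start=1):
        tok = line.split()
        if tuple(tok[:3]) == _CATALYTIC_PREFIX:
            if len(tok) != 7:
                raise StructureError(
                    f"line {lineno}: malformed catalytic remark {line!r}")
            out.append(CatalyticAnnotation(
                block_index=int(tok[3]), chain=tok[4], number=int(tok[5]),
                name3=tok[6]))
    return out


def read_pdb(path, ligand_name: str = "",
             ligand_topology: LigandTopology | None = None) -> Structure:
    """Read a PDB file into a Structure.

    HETATM residues (or residues matching ``ligand_name``) become ligands;
    REMARK 999 CATALYTIC lines populate the catalytic annotations.  When a
    ligand topology is supplied, ligand atoms inherit its polarity flags.
    """
    path = Path(path)
    if ligand_topology is not None and not ligand_name:
        ligand_name = ligand_topology.name3
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from None
    annotations = _parse_catalytic_remarks(path.read_text().splitlines())

    residues: list = []
    ligands: list = []
    seen_altloc = False
    for model in st:
        for chain in model:
            for gres in chain:
                is_lig = (gres.name == ligand_name
                          or (gres.het_flag == "H" and gres.name != "HOH"
                              and gres.name not in RESIDUE_TOPOLOGIES))
                res = Residue(name3=gres.name, chain=chain.name,
                              number=gres.seqid.num, is_ligand=is_lig)
                for ga in gres:
                    if ga.altloc not in ("", "A", "\x00"):
                        seen_altloc = True
                        continue
                    el = ga.element.name if ga.element else ga.name[0]
                    if el.upper() == "H":
                        continue
                    atom = Atom(ga.name, el,
                                np.array([ga.pos.x, ga.pos.y, ga.pos.z]))
                    if is_lig and ligand_topology is not None:
                        try:
                            la = ligand_topology.atom(ga.name)
                            atom.donor, atom.acceptor = la.donor, la.acceptor
                        except KeyError:
                            pass
                    elif not is_lig:
                        annotate_protein_atom(gres.name, atom)
                    res.atoms[ga.name] = atom
                (ligands if is_lig else residues).append(res)
        break  # first model only
    struct = Structure(residues=residues, ligands=ligands,
                       annotations=annotations)
    for ann in annotations:
        struct.find(ann.chain, ann.number)  # validates references
    return struct


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure to PDB, including catalytic annotation remarks."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict = {}

    def add(res: Residue, het: bool):
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name3
        gres.seqid = gemmi.SeqId(res.number, " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*map(float, a.xyz))
            ga.occ = 1.0
            gres.add_atom(ga)
        chains[res.chain].add_residue(gres)

    for res in structure.residues:
        add(res, het=False)
    for lig in structure.ligands:
        add(lig, het=True)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.raw_remarks = [
        f"REMARK 999 CATALYTIC {a.block_index} {a.chain} {a.number} {a.name3}"
        for a in sorted(structure.annotations, key=lambda a: a.block_index)
    ]
    st.write_pdb(str(path))
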