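"""Chemical reference data: amino-acid side-chain topologies, atom types, radii.

Residue side chains are described in internal coordinates so that rotamers can
be rebuilt from chi angles off an existing backbone.  Each side-chain heavy
atom carries a reference triple (parent, ref2, ref3), an ideal bond length and
bond angle, and a torsion specification: either a rotatable chi (optionally
with a fixed branch offset, e.g. OD2 = chi2 + 180 on Asp) or a fixed value for
rigid ring atoms.

Only heavy atoms are modelled.  Polarity (hydrogen-bond donor/acceptor
capability) is flagged on the heavy atom itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# van der Waals radii by element (A)
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}
STANDARD_AA3 = set(AA3TO1)

# amino acids allowed at designable positions (everything but cysteine)
DESIGNABLE_AA3 = sorted(STANDARD_AA3 - {"CYS"})

# canonical chi samples of the reduced rotamer library (gauche-/trans/gauche+)
CHI_SAMPLES = (-60.0, 180.0, 60.0)
# extra-sample offset applied about each canonical value by -ex1/-ex2
EX_DELTA = 30.0


@dataclass(frozen=True)
class SideChainAtom:
    """One side-chain heavy atom in internal coordinates.

    ``torsion`` is ``("chi", k, offset)`` meaning
    dihedral(ref3, ref2, parent, self) = chi_k + offset, or
    ``("fix", value, 0.0)`` for rigid (ring) atoms.
    """

    name: str
    element: str
    atom_type: str
    parent: str
    ref2: str
    ref3: str
    bond: float
    angle: float
    torsion: tuple
    donor: bool = False
    acceptor: bool = False


def _chi(k: int, offset: float = 0.0) -> tuple:
    return ("chi", k, offset)


def _fix(value: float) -> tuple:
    return ("fix", value, 0.0)


@dataclass(frozen=True)
class ResidueTopology:
    name3: str
    n_chi: int
    side_chain: tuple  # tuple[SideChainAtom, ...]; excludes CB
    has_cb: bool = True

    @property
    def chi_atoms(self) -> list:
        """For chi_k, the four atom names defining it."""
        chain = ["N", "CA", "CB"]
        for a in self.side_chain:
            if a.torsion[0] == "chi" and a.torsion[2] == 0.0:
                if a.torsion[1] == len(chain) - 2:
                    chain.append(a.name)
        out = []
        for k in range(1, self.n_chi + 1):
            out.append(tuple(chain[k - 1:k + 3]))
        return out

    def atom_names(self) -> list:
        names = ["N", "CA", "C", "O"]
        if self.has_cb:
            names.append("CB")
        names.extend(a.name for a in self.side_chain)
        return names

    def parent_of(self, name: str) -> str | None:
        """Parent in the tree rooted at the backbone, growing along the side chain."""
        table = {"CA": "N", "C": "CA", "O": "C", "CB": "CA", "N": None}
        if name in table:
            return table[name]
        for a in self.side_chain:
            if a.name == name:
                return a.parent
        raise KeyError(f"{self.name3} has no atom {name!r}")

    def atoms_of_type(self, type_symbol: str) -> list:
        return [a.name for a in self.side_chain if a.atom_type == type_symbol]


def _sc(name, element, atype, parent, ref2, ref3, bond, angle, torsion,
        donor=False, acceptor=False):
    return SideChainAtom(name, element, atype, parent, ref2, ref3,
                         bond, angle, torsion, donor, acceptor)


def _topo(name3, n_chi, atoms, has_cb=True):
    return ResidueTopology(name3, n_chi, tuple(atoms), has_cb)


RESIDUE_TOPOLOGIES = {t.name3: t for t in [
    _topo("GLY", 0, [], has_cb=False),
    _topo("ALA", 0, []),
    _topo("SER", 1, [
        _sc("OG", "O", "OH", "CB", "CA", "N", 1.42, 110.8, _chi(1),
            donor=True, acceptor=True),
    ]),
    _topo("CYS", 1, [
        _sc("SG", "S", "S", "CB", "CA", "N", 1.81, 114.4, _chi(1)),
    ]),
    _topo("THR", 1, [
        _sc("OG1", "O", "OH", "CB", "CA", "N", 1.42, 109.5, _chi(1),
            donor=True, acceptor=True),
        _sc("CG2", "C", "CH3", "CB", "CA", "N", 1.52, 110.5, _chi(1, -120.0)),
    ]),
    _topo("VAL", 1, [
        _sc("CG1", "C", "CH3", "CB", "CA", "N", 1.52, 110.5, _chi(1)),
        _sc("CG2", "C", "CH3", "CB", "CA", "N", 1.52, 110.5, _chi(1, 122.0)),
    ]),
    _topo("LEU", 2, [
        _sc("CG", "C", "CH1", "CB", "CA", "N", 1.53, 116.3, _chi(1)),
        _sc("CD1", "C", "CH3", "CG", "CB", "CA", 1.52, 110.7, _chi(2)),
        _sc("CD2", "C", "CH3", "CG", "CB", "CA", 1.52, 110.7, _chi(2, 122.0)),
    ]),
    _topo("ILE", 2, [
        _sc("CG1", "C", "CH2", "CB", "CA", "N", 1.53, 110.4, _chi(1)),
        _sc("CG2", "C", "CH3", "CB", "CA", "N", 1.52, 110.5, _chi(1, -122.0)),
        _sc("CD1", "C", "CH3", "CG1", "CB", "CA", 1.51, 113.8, _chi(2)),
    ]),
    _topo("MET", 3, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        _sc("SD", "S", "S", "CG", "CB", "CA", 1.80, 112.7, _chi(2)),
        _sc("CE", "C", "CH3", "SD", "CG", "CB", 1.79, 100.9, _chi(3)),
    ]),
    _topo("PHE", 2, [
        _sc("CG", "C", "aroC", "CB", "CA", "N", 1.50, 113.8, _chi(1)),
        _sc("CD1", "C", "aroC", "CG", "CB", "CA", 1.39, 120.8, _chi(2)),
        _sc("CD2", "C", "aroC", "CG", "CB", "CA", 1.39, 120.8, _chi(2, 180.0)),
        _sc("CE1", "C", "aroC", "CD1", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        _sc("CE2", "C", "aroC", "CD2", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        _sc("CZ", "C", "aroC", "CE1", "CD1", "CG", 1.39, 120.0, _fix(0.0)),
    ]),
    _topo("TYR", 2, [
        _sc("CG", "C", "aroC", "CB", "CA", "N", 1.50, 113.8, _chi(1)),
        _sc("CD1", "C", "aroC", "CG", "CB", "CA", 1.39, 120.8, _chi(2)),
        _sc("CD2", "C", "aroC", "CG", "CB", "CA", 1.39, 120.8, _chi(2, 180.0)),
        _sc("CE1", "C", "aroC", "CD1", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        _sc("CE2", "C", "aroC", "CD2", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        _sc("CZ", "C", "aroC", "CE1", "CD1", "CG", 1.39, 120.0, _fix(0.0)),
        _sc("OH", "O", "OH", "CZ", "CE1", "CD1", 1.38, 120.0, _fix(180.0),
            donor=True, acceptor=True),
    ]),
    _topo("TRP", 2, [
        _sc("CG", "C", "aroC", "CB", "CA", "N", 1.50, 113.6, _chi(1)),
        _sc("CD1", "C", "aroC", "CG", "CB", "CA", 1.37, 126.9, _chi(2)),
        _sc("CD2", "C", "aroC", "CG", "CB", "CA", 1.43, 126.7, _chi(2, 180.0)),
        _sc("NE1", "N", "Ntrp", "CD1", "CG", "CB", 1.38, 110.2, _fix(180.0),
            donor=True),
        _sc("CE2", "C", "aroC", "CD2", "CG", "CB", 1.41, 107.2, _fix(180.0)),
        _sc("CE3", "C", "aroC", "CD2", "CG", "CB", 1.40, 133.9, _fix(0.0)),
        _sc("CZ2", "C", "aroC", "CE2", "CD2", "CG", 1.40, 122.4, _fix(180.0)),
        _sc("CZ3", "C", "aroC", "CE3", "CD2", "CG", 1.39, 118.8, _fix(180.0)),
        _sc("CH2", "C", "aroC", "CZ2", "CE2", "CD2", 1.37, 117.5, _fix(180.0)),
    ]),
    _topo("ASP", 2, [
        _sc("CG", "C", "COO", "CB", "CA", "N", 1.52, 113.0, _chi(1)),
        _sc("OD1", "O", "OOC", "CG", "CB", "CA", 1.25, 119.0, _chi(2),
            acceptor=True),
        _sc("OD2", "O", "OOC", "CG", "CB", "CA", 1.25, 119.0, _chi(2, 180.0),
            acceptor=True),
    ]),
    _topo("GLU", 3, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        _sc("CD", "C", "COO", "CG", "CB", "CA", 1.52, 112.6, _chi(2)),
        _sc("OE1", "O", "OOC", "CD", "CG", "CB", 1.25, 119.0, _chi(3),
            acceptor=True),
        _sc("OE2", "O", "OOC", "CD", "CG", "CB", 1.25, 119.0, _chi(3, 180.0),
            acceptor=True),
    ]),
    _topo("ASN", 2, [
        _sc("CG", "C", "CNH2", "CB", "CA", "N", 1.52, 112.7, _chi(1)),
        _sc("OD1", "O", "ONH2", "CG", "CB", "CA", 1.23, 120.8, _chi(2),
            acceptor=True),
        _sc("ND2", "N", "NH2O", "CG", "CB", "CA", 1.33, 116.4, _chi(2, 180.0),
            donor=True),
    ]),
    _topo("GLN", 3, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        _sc("CD", "C", "CNH2", "CG", "CB", "CA", 1.52, 112.6, _chi(2)),
        _sc("OE1", "O", "ONH2", "CD", "CG", "CB", 1.23, 120.8, _chi(3),
            acceptor=True),
        _sc("NE2", "N", "NH2O", "CD", "CG", "CB", 1.33, 116.4, _chi(3, 180.0),
            donor=True),
    ]),
    _topo("HIS", 2, [
        _sc("CG", "C", "aroC", "CB", "CA", "N", 1.50, 113.8, _chi(1)),
        _sc("ND1", "N", "Nhis", "CG", "CB", "CA", 1.38, 122.7, _chi(2),
            donor=True, acceptor=True),
        _sc("CD2", "C", "aroC", "CG", "CB", "CA", 1.36, 131.0, _chi(2, 180.0)),
        _sc("CE1", "C", "aroC", "ND1", "CG", "CB", 1.32, 109.0, _fix(180.0)),
        _sc("NE2", "N", "Nhis", "CD2", "CG", "CB", 1.37, 107.0, _fix(180.0),
            donor=True, acceptor=True),
    ]),
    _topo("LYS", 4, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        _sc("CD", "C", "CH2", "CG", "CB", "CA", 1.52, 111.3, _chi(2)),
        _sc("CE", "C", "CH2", "CD", "CG", "CB", 1.52, 111.3, _chi(3)),
        _sc("NZ", "N", "Nlys", "CE", "CD", "CG", 1.49, 111.0, _chi(4),
            donor=True),
    ]),
    _topo("ARG", 4, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        _sc("CD", "C", "CH2", "CG", "CB", "CA", 1.52, 111.3, _chi(2)),
        _sc("NE", "N", "Narg", "CD", "CG", "CB", 1.46, 112.0, _chi(3),
            donor=True),
        _sc("CZ", "C", "aroC", "NE", "CD", "CG", 1.33, 124.2, _chi(4)),
        _sc("NH1", "N", "Narg", "CZ", "NE", "CD", 1.33, 120.0, _fix(0.0),
            donor=True),
        _sc("NH2", "N", "Narg", "CZ", "NE", "CD", 1.33, 120.0, _fix(180.0),
            donor=True),
    ]),
    # proline ring closure (CD-N bond) is not enforced; the two-chi chain
    # approximation is adequate for packing at this scale
    _topo("PRO", 2, [
        _sc("CG", "C", "CH2", "CB", "CA", "N", 1.49, 104.5, _chi(1)),
        _sc("CD", "C", "CH2", "CG", "CB", "CA", 1.50, 106.1, _chi(2)),
    ]),
]}

# backbone polarity: amide N donates (except PRO), carbonyl O accepts
BACKBONE_DONOR = {"N"}
BACKBONE_ACCEPTOR = {"O"}

# ideal backbone internal coordinates used when building side chains / chains
BACKBONE_GEOMETRY = {
    "N_CA": 1.458, "CA_C": 1.523, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7,
    "CA_C_O": 120.8, "CA_CB": 1.530, "N_CA_CB": 110.5,
    # dihedral(C, N, CA, CB) for an L-amino acid
    "CB_IMPROPER": -122.6,
}


def expand_residue1(code: str) -> list:
    """Expand a 1-letter residue string ('ED') to 3-letter names (['GLU','ASP'])."""
    out = []
    for c in code:
        if c.upper() not in AA1TO3:
            raise ValueError(f"unknown 1-letter residue code {c!r} in {code!r}")
        name3 = AA1TO3[c.upper()]
        if name3 not in out:
            out.append(name3)
    return out
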