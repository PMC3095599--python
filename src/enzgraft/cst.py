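"""The geometric-constraint file (cstfile): a theozyme as text.

A theozyme — a minimal active-site model of a ligand (transition state) plus
disembodied catalytic groups at idealized geometry — is written as one block
per catalytic interaction:

    CST::BEGIN
      TEMPLATE::   ATOM_MAP: 1 atom_name: C1 C2 O2
      TEMPLATE::   ATOM_MAP: 1 residue3: 1n1
      TEMPLATE::   ATOM_MAP: 2 atom_type: OOC,
      TEMPLATE::   ATOM_MAP: 2 residue1: ED
      CONSTRAINT:: distanceAB:    3.06   0.2  100.  0    0
      CONSTRAINT:: angle_A:      73.60  10.0   80.0 360. 1
      ...
    CST::END

Each ATOM_MAP names one of the two partners (1 or 2) either by an explicit
ordered atom triple (``atom_name``) or by an atom type (``atom_type``), in
which case the base atom and its base complete the triple and any atom of
that type may satisfy the constraint (the lowest-scoring one is used).
``residue3``/``residue1`` restrict the partner's residue type; multi-letter
``residue1`` strings expand per letter ('ED' -> Glu, Asp).

CONSTRAINT records carry x0, xtol, k, then the covalent flag (distanceAB) or
periodicity (angular parameters), and optionally the matcher sample count n;
the classic matcher samples 2n+1 points spanning [x0-xtol, x0+xtol] around
every periodic copy of x0.

Lines beginning with '#' are comments.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import STANDARD_AA3, expand_residue1
from .geometry import PARAM_NAMES

# periodic copies closer than this (degrees) are considered duplicates
_COPY_DEDUP_TOL = 1e-6


class CstParseError(ValueError):
    """Malformed cstfile content; message carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class AtomMapSpec:
    """One partner of a constraint block: which atoms, which residue types."""

    which: int                      # catalytic partner index, 1 or 2
    mode: str                       # "by_name" | "by_type"
    names: tuple = ()               # ordered atom triple (by_name)
    type_symbol: str = ""           # atom-type token (by_type)
    allowed_residues: tuple = ()    # residue-type names

    def validate(self) -> None:
        if self.which not in (1, 2):
            raise ValueError(f"ATOM_MAP partner index must be 1 or 2, got {self.which}")
        if self.mode == "by_name":
            if len(self.names) != 3:
                raise ValueError("atom_name map needs exactly 3 atom names")
        elif self.mode == "by_type":
            if not self.type_symbol:
                raise ValueError("atom_type map needs exactly 1 type symbol")
        else:
            raise ValueError(f"unknown atom map mode {self.mode!r}")
        if not self.allowed_residues:
            raise ValueError("atom map has no allowed residue types")

    @property
    def is_ligand(self) -> bool:
        """A map whose residue set contains a non-standard code names the ligand."""
        return any(r not in STANDARD_AA3 for r in self.allowed_residues)


@dataclass
class ConstraintParam:
    """One geometric parameter of a block: ideal value, tolerance, strength.

    ``fourth`` is the covalent flag (0/1) for distanceAB and the periodicity
    in degrees for the angular parameters.  ``n_samples`` is the matcher's n:
    2n+1 points are placed across the tolerance window.
    """

    name: str
    x0: float
    xtol: float
    k: float
    fourth: float
    n_samples: int = 0

    def validate(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ValueError(f"unknown constraint parameter {self.name!r}")
        if self.xtol < 0:
            raise ValueError(f"{self.name}: xtol must be >= 0")
        if self.k < 0:
            raise ValueError(f"{self.name}: force constant must be >= 0")
        if self.n_samples < 0:
            raise ValueError(f"{self.name}: sample count must be >= 0")
        if self.name == "distanceAB":
            if self.fourth not in (0.0, 1.0):
                raise ValueError("distanceAB covalent flag must be 0 or 1")
        elif self.fourth <= 0:
            raise ValueError(f"{self.name}: periodicity must be > 0")

    @property
    def is_covalent(self) -> bool:
        return self.name == "distanceAB" and self.fourth == 1.0


@dataclass
class ConstraintBlock:
    """One catalytic interaction: two atom maps plus up to six parameters.

    ``algorithm`` (classic | secondary) is a matcher assignment and lives in
    configuration, not in the cstfile itself; classic is the default.
    """

    map1: AtomMapSpec
    map2: AtomMapSpec
    params: dict                    # name -> ConstraintParam
    algorithm: str = "classic"

    def validate(self) -> None:
        self.map1.validate()
        self.map2.validate()
        if self.map1.which != 1 or self.map2.which != 2:
            raise ValueError("block maps must carry partner indices 1 and 2")
        if self.algorithm not in ("classic", "secondary"):
            raise ValueError(f"unknown matching algorithm {self.algorithm!r}")
        for name, p in self.params.items():
            if name != p.name:
                raise ValueError("parameter dict key disagrees with parameter name")
            p.validate()
        if self.algorithm == "classic":
            missing = [n for n in PARAM_NAMES if n not in self.params]
            if missing:
                raise ValueError(
                    "classic matching requires sample values for all 6 parameters; "
                    f"missing {', '.join(missing)}"
                )

    @property
    def ligand_map(self) -> AtomMapSpec:
        for m in (self.map1, self.map2):
            if m.is_ligand:
                return m
        raise ValueError("block has no ligand partner")

    @property
    def protein_map(self) -> AtomMapSpec:
        for m in (self.map1, self.map2):
            if not m.is_ligand:
                return m
        raise ValueError("block has no protein partner")


@dataclass
class Theozyme:
    """An ordered list of constraint blocks plus the ligand's 3-letter code."""

    blocks: list
    ligand_name: str = ""

    def __post_init__(self):
        if not self.ligand_name and self.blocks:
            for block in self.blocks:
                try:
                    self.ligand_name = block.ligand_map.allowed_residues[0]
                    break
                except ValueError:
                    continue

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("theozyme must contain at least one constraint block")
        if self.blocks[0].algorithm != "classic":
            raise ValueError(
                "classic matching must be used for the first theozyme interaction"
            )
        for b in self.blocks:
            b.validate()
        if not self.ligand_name:
            raise ValueError("theozyme names no ligand residue type")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_number(token: str, line: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise CstParseError(f"expected a number, got {token!r}", line) from None


def _finish_block(maps: dict, params: dict, begin_line: int) -> ConstraintBlock:
    for which in (1, 2):
        if which not in maps:
            raise CstParseError(f"block lacks ATOM_MAP records for partner {which}",
                                begin_line)
        spec = maps[which]
        if spec["mode"] is None:
            raise CstParseError(
                f"partner {which} has neither atom_name nor atom_type", begin_line)
        if not spec["residues"]:
            raise CstParseError(
                f"partner {which} has no residue1/residue3 record", begin_line)

    def build(which: int) -> AtomMapSpec:
        spec = maps[which]
        m = AtomMapSpec(
            which=which,
            mode=spec["mode"],
            names=tuple(spec["names"]),
            type_symbol=spec["type"],
            allowed_residues=tuple(spec["residues"]),
        )
        m.validate()
        return m

    return ConstraintBlock(map1=build(1), map2=build(2), params=params)


def parse_cstfile(text) -> Theozyme:
    """Parse cstfile text (a string or text stream) into a Theozyme.

    The result is structurally validated per record; theozyme-level
    invariants (at least one block, classic first) are checked by
    ``Theozyme.validate`` which callers should invoke before use.
    """
    if hasattr(text, "read"):
        text = text.read()
    blocks: list = []
    in_block = False
    begin_line = 0
    maps: dict = {}
    params: dict = {}

    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        record = tokens[0]

        if record == "CST::BEGIN":
            if in_block:
                raise CstParseError("CST::BEGIN inside an open block", lineno)
            in_block = True
            begin_line = lineno
            maps = {1: {"mode": None, "names": [], "type": "", "residues": []},
                    2: {"mode": None, "names": [], "type": "", "residues": []}}
            params = {}
            continue

        if record == "CST::END":
            if not in_block:
                raise CstParseError("CST::END without matching CST::BEGIN", lineno)
            blocks.append(_finish_block(maps, params, begin_line))
            in_block = False
            continue

        if not in_block:
            raise CstParseError(f"record outside CST::BEGIN/CST::END: {line!r}", lineno)

        if record == "TEMPLATE::":
            if len(tokens) < 4 or tokens[1] != "ATOM_MAP:":
                raise CstParseError(f"malformed TEMPLATE record: {line!r}", lineno)
            which = int(_parse_number(tokens[2], lineno))
            if which not in (1, 2):
                raise CstParseError(f"ATOM_MAP partner must be 1 or 2, got {which}", lineno)
            tag = tokens[3].rstrip(":") + ":"
            values = [t.rstrip(",") for t in tokens[4:]]
            spec = maps[which]
            if tag == "atom_name:":
                if spec["mode"] == "by_type":
                    raise CstParseError(
                        "both atom_name and atom_type given for one partner", lineno)
                if len(values) != 3:
                    raise CstParseError(
                        f"atom_name needs 3 atom names, got {len(values)}", lineno)
                spec["mode"] = "by_name"
                spec["names"] = values
            elif tag == "atom_type:":
                if spec["mode"] == "by_name":
                    raise CstParseError(
                        "both atom_name and atom_type given for one partner", lineno)
                if len(values) != 1:
                    raise CstParseError("atom_type needs exactly 1 type symbol", lineno)
                spec["mode"] = "by_type"
                spec["type"] = values[0]
            elif tag == "residue3:":
                spec["residues"].extend(v.upper() if v.upper() in STANDARD_AA3 else v
                                        for v in values)
            elif tag == "residue1:":
                if len(values) != 1:
                    raise CstParseError("residue1 takes one code string", lineno)
                try:
                    spec["residues"].extend(expand_residue1(values[0]))
                except ValueError as exc:
                    raise CstParseError(str(exc), lineno) from None
            else:
                raise CstParseError(f"unknown ATOM_MAP tag {tokens[3]!r}", lineno)
            continue

        if record == "CONSTRAINT::":
            if len(tokens) < 6:
                raise CstParseError(f"truncated CONSTRAINT record: {line!r}", lineno)
            name = tokens[1].rstrip(":")
            if name not in PARAM_NAMES:
                raise CstParseError(f"unknown constraint parameter {name!r}", lineno)
            if name in params:
                raise CstParseError(f"duplicate parameter {name!r} in block", lineno)
            numbers = [_parse_number(t, lineno) for t in tokens[2:]]
            if len(numbers) not in (4, 5):
                raise CstParseError(
                    f"{name} takes 4 or 5 numeric columns, got {len(numbers)}", lineno)
            n_samples = int(numbers[4]) if len(numbers) == 5 else 0
            if len(numbers) == 5 and numbers[4] != n_samples:
                raise CstParseError("sample count must be an integer", lineno)
            p = ConstraintParam(name=name, x0=numbers[0], xtol=numbers[1],
                                k=numbers[2], fourth=numbers[3], n_samples=n_samples)
            try:
                p.validate()
            except ValueError as exc:
                raise CstParseError(str(exc), lineno) from None
            params[name] = p
            continue

        raise CstParseError(f"unknown record {record!r}", lineno)

    if in_block:
        raise CstParseError("CST::BEGIN without matching CST::END", begin_line)
    return Theozyme(blocks=blocks)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # enough significant digits for exact float round trips at printed scale
    return f"{v:.10g}"


def write_cstfile(theozyme: Theozyme) -> str:
    """Serialize a Theozyme; ``parse_cstfile(write_cstfile(t))`` == t field-for-field."""
    out = []
    for block in theozyme.blocks:
        out.append("CST::BEGIN")
        for m in (block.map1, block.map2):
            if m.mode == "by_name":
                out.append(f"  TEMPLATE::   ATOM_MAP: {m.which} atom_name: "
                           + " ".join(m.names))
            else:
                out.append(f"  TEMPLATE::   ATOM_MAP: {m.which} atom_type: "
                           f"{m.type_symbol},")
            out.append(f"  TEMPLATE::   ATOM_MAP: {m.which} residue3: "
                       + " ".join(m.allowed_residues))
        for name in PARAM_NAMES:
            if name in block.params:
                p = block.params[name]
                cols = [_fmt(p.x0), _fmt(p.xtol), _fmt(p.k), _fmt(p.fourth),
                        str(p.n_samples)]
                out.append(f"  CONSTRAINT:: {name + ':':<12} " + "  ".join(cols))
        out.append("CST::END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# sample enumeration
# ---------------------------------------------------------------------------

def periodic_copies(x0: float, per: float) -> list:
    """Distinct periodic copies of x0 within one full 360-degree turn.

    Copies x0 + m*per are wrapped to [0, 360) and deduplicated (1e-6 deg);
    ``per`` need not divide 360.
    """
    if per <= 0:
        raise ValueError("periodicity must be positive")
    copies: list = []
    m = 0
    base = x0 % 360.0
    n_turn = max(1, math.ceil(360.0 / per) + 1)
    for m in range(n_turn + 1):
        c = (base + m * per) % 360.0
        if not any(abs(c - o) < _COPY_DEDUP_TOL
                   or abs(abs(c - o) - 360.0) < _COPY_DEDUP_TOL for o in copies):
            copies.append(c)
    return sorted(copies)


def enumerate_samples(param: ConstraintParam) -> list:
    """The classic matcher's sample values for one parameter.

    2*n+1 equally spaced values spanning [c - xtol, c + xtol] around every
    periodic copy c of x0 (the single x0 for distanceAB), sorted ascending.
    """
    param.validate()
    n = param.n_samples
    if param.name == "distanceAB":
        centers = [param.x0]
    else:
        centers = periodic_copies(param.x0, param.fourth)
    values: list = []
    for c in centers:
        if n == 0:
            values.append(c)
        else:
            step = param.xtol / n
            values.extend(c + i * step for i in range(-n, n + 1))
    return sorted(values)


def placement_count(block: ConstraintBlock) -> int:
    """Number of ligand placements the classic matcher attempts per rotamer.

    The product over all six parameters of their sample-list lengths.
    """
    missing = [n for n in PARAM_NAMES if n not in block.params]
    if missing:
        raise ValueError(
            "placement count needs all six parameters; missing "
            + ", ".join(missing)
        )
    count = 1
    for name in PARAM_NAMES:
        count *= len(enumerate_samples(block.params[name]))
    return count


# ---------------------------------------------------------------------------
# atom-triple resolution
# ---------------------------------------------------------------------------

def resolve_atom_triples(amap: AtomMapSpec, topology) -> list:
    """Candidate (atom1, atom2, atom3) name triples for one atom map.

    ``topology`` must expose ``atom_names()``, ``parent_of(name)`` and
    ``atoms_of_type(symbol)`` — both residue topologies and ligand topologies
    do.  by_name maps return their single stated triple; by_type maps return
    one triple per matching atom, completed by the atom's base (parent) and
    its base, and downstream scoring takes the lowest-scoring triple.  An
    empty list means this residue type cannot satisfy the map.
    """
    if amap.mode == "by_name":
        known = set(topology.atom_names())
        for name in amap.names:
            if name not in known:
                raise KeyError(f"atom {name!r} absent from topology")
        return [tuple(amap.names)]

    triples = []
    for atom in topology.atoms_of_type(amap.type_symbol):
        p1 = topology.parent_of(atom)
        p2 = topology.parent_of(p1) if p1 else None
        if p1 is None or p2 is None:
            raise ValueError(
                f"typed atom {atom!r} has fewer than 2 ancestors; cannot form triple")
        triples.append((atom, p1, p2))
    return triples
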