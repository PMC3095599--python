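"""Deterministic synthetic inputs: toy scaffolds, ligand, theozyme, planted sites.

Everything the pipeline consumes can be generated here with no external
downloads: an idealized-geometry pocket scaffold (two antiparallel helices
over a strand floor, single chain with numbering gaps at the segment
junctions), a simplified dihydroxyacetone-phosphate analog (phosphate
omitted: C1/C2/C3 plus carbonyl O1 and hydroxyl O2), a three-interaction
triosephosphate-isomerase-style theozyme (Glu/Asp base, His polarizing the
carbonyl, Lys polarizing the hydroxyl; the Lys block leaves torsion_AB and
torsion_B unconstrained and is matched with the secondary algorithm), and a
planted-site constructor that guarantees, by inverse construction, a ground
truth match whose restraint score is exactly zero.

The theozyme's numeric geometries are fixture data chosen to be chemically
sensible hydrogen-bond geometries; they are not taken from any reference
enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .chem import CHI_SAMPLES, RESIDUE_TOPOLOGIES
from .cst import (AtomMapSpec, ConstraintBlock, ConstraintParam, Theozyme,
                  resolve_atom_triples, write_cstfile)
from .geometry import ParamTuple
from .matcher import MatchConfig, scaffold_backbone_arrays
from .structure import (Atom, IcoorRecord, LigandAtom, LigandTopology,
                        Residue, Structure, build_side_chain,
                        write_ligand_params, write_pdb)

LIGAND_NAME = "DHP"


# ---------------------------------------------------------------------------
# ligand
# ---------------------------------------------------------------------------

def make_dhap_ligand() -> LigandTopology:
    """A simplified DHAP analog: C3 backbone, carbonyl O1 on C2, hydroxyl O2 on C1."""
    topo = LigandTopology(
        name3=LIGAND_NAME,
        atoms=[
            LigandAtom("C2", "C", "CC"),
            LigandAtom("C1", "C", "CH2"),
            LigandAtom("O1", "O", "Oal", acceptor=True),
            LigandAtom("C3", "C", "CH3"),
            LigandAtom("O2", "O", "OH", donor=True, acceptor=True),
        ],
        bonds=[("C1", "C2"), ("C2", "O1"), ("C2", "C3"), ("C1", "O2")],
        icoor=[
            IcoorRecord("C2", 0.0, 0.0, 0.0, "C2", "C2", "C2"),
            IcoorRecord("C1", 1.52, 0.0, 0.0, "C2", "C2", "C2"),
            IcoorRecord("O1", 1.23, 121.0, 0.0, "C2", "C1", "C1"),
            IcoorRecord("C3", 1.52, 116.5, 180.0, "C2", "C1", "O1"),
            IcoorRecord("O2", 1.42, 111.0, 120.0, "C1", "C2", "O1"),
        ],
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# theozyme
# ---------------------------------------------------------------------------

def _param(name, x0, xtol, k, fourth, n=0):
    return ConstraintParam(name=name, x0=x0, xtol=xtol, k=k, fourth=fourth,
                           n_samples=n)


def make_theozyme_tim() -> tuple:
    """Three-interaction TIM-style theozyme plus the matching ligand topology.

    Blocks 1 and 2 (carboxylate base at C1; His at the carbonyl O1) define
    all six parameters and are matched classically; block 3 (Lys at the
    hydroxyl O2) constrains only distance, the two angles and torsion_A and
    is matched with the secondary algorithm.
    """
    ligand = make_dhap_ligand()

    block1 = ConstraintBlock(
        map1=AtomMapSpec(which=1, mode="by_name", names=("C1", "C2", "O2"),
                         allowed_residues=(LIGAND_NAME,)),
        map2=AtomMapSpec(which=2, mode="by_type", type_symbol="OOC",
                         allowed_residues=("GLU", "ASP")),
        params={
            "distanceAB": _param("distanceAB", 3.10, 0.2, 100.0, 0),
            "angle_A": _param("angle_A", 107.0, 10.0, 80.0, 360.0, 1),
            "angle_B": _param("angle_B", 120.0, 15.0, 80.0, 360.0, 1),
            "torsion_A": _param("torsion_A", -105.0, 15.0, 60.0, 360.0, 1),
            "torsion_AB": _param("torsion_AB", 180.0, 90.0, 0.0, 360.0, 1),
            "torsion_B": _param("torsion_B", 180.0, 15.0, 60.0, 360.0, 1),
        },
        algorithm="classic",
    )
    block2 = ConstraintBlock(
        map1=AtomMapSpec(which=1, mode="by_name", names=("O1", "C2", "C1"),
                         allowed_residues=(LIGAND_NAME,)),
        map2=AtomMapSpec(which=2, mode="by_type", type_symbol="Nhis",
                         allowed_residues=("HIS",)),
        params={
            "distanceAB": _param("distanceAB", 2.90, 0.2, 100.0, 0),
            "angle_A": _param("angle_A", 120.0, 10.0, 80.0, 360.0, 1),
            "angle_B": _param("angle_B", 125.0, 15.0, 80.0, 360.0, 1),
            "torsion_A": _param("torsion_A", 180.0, 15.0, 60.0, 360.0, 1),
            "torsion_AB": _param("torsion_AB", 0.0, 60.0, 0.0, 360.0, 1),
            "torsion_B": _param("torsion_B", 180.0, 20.0, 60.0, 180.0, 0),
        },
        algorithm="classic",
    )
    block3 = ConstraintBlock(
        map1=AtomMapSpec(which=1, mode="by_name", names=("O2", "C1", "C2"),
                         allowed_residues=(LIGAND_NAME,)),
        map2=AtomMapSpec(which=2, mode="by_type", type_symbol="Nlys",
                         allowed_residues=("LYS",)),
        params={
            "distanceAB": _param("distanceAB", 2.90, 0.3, 100.0, 0),
            "angle_A": _param("angle_A", 109.5, 15.0, 80.0, 360.0),
            "angle_B": _param("angle_B", 109.5, 15.0, 80.0, 360.0),
            "torsion_A": _param("torsion_A", -90.0, 30.0, 60.0, 360.0),
        },
        algorithm="secondary",
    )
    theozyme = Theozyme(blocks=[block1, block2, block3])
    theozyme.validate()
    return theozyme, ligand


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

from .chem import BACKBONE_GEOMETRY as BB


def build_backbone_segment(n_res: int, phi: float, psi: float,
                           omega: float = 180.0) -> list:
    """Ideal-geometry backbone (N, CA, C, O dicts) for a repeating phi/psi."""
    coords = []
    n = np.array([0.0, 0.0, 0.0])
    ca = n + np.array([BB["N_CA"], 0.0, 0.0])
    th = np.radians(BB["N_CA_C"])
    c = ca + BB["CA_C"] * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
    for i in range(n_res):
        res = {"N": n, "CA": ca, "C": c}
        n_next = geometry.place_atom(n, ca, c, BB["C_N"], BB["CA_C_N"], psi)
        res["O"] = geometry.place_atom(n, ca, c, BB["C_O"], BB["CA_C_O"],
                                       psi - 180.0)
        coords.append(res)
        ca_next = geometry.place_atom(ca, c, n_next, BB["N_CA"], BB["C_N_CA"],
                                      omega)
        c_next = geometry.place_atom(c, n_next, ca_next, BB["CA_C"],
                                     BB["N_CA_C"], phi)
        n, ca, c = n_next, ca_next, c_next
    return coords


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along increasing residue index
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree turn about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _place_segment(coords: list, target_axis, target_center) -> list:
    cas = np.stack([r["CA"] for r in coords])
    axis = _principal_axis(cas)
    R = _rotation_between(axis, np.asarray(target_axis, float)
                          / np.linalg.norm(target_axis))
    center = cas.mean(axis=0)
    out = []
    for r in coords:
        out.append({k: R @ (v - center) + np.asarray(target_center, float)
                    for k, v in r.items()})
    return out


# residues numbered from here occlude the pocket (negative-control scaffolds)
OCCLUDER_START = 401


def make_toy_scaffold(n_residues: int = 32, seed: int = 0,
                      occluded: bool = False) -> Structure:
    """A poly-ALA pocket scaffold: two antiparallel helices over a strand floor.

    One chain with numbering gaps between segments (unresolved-loop style).
    The pocket opens toward +z around the origin.  Deterministic per seed;
    the seed jitters the helix separation slightly.

    With ``occluded=True`` the pocket volume is filled with additional strand
    segments (residue numbers from ``OCCLUDER_START``), so no collision-free
    ligand placement exists within reach of the pocket-lining side chains —
    a negative control for matching.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues for a pocket scaffold")
    rng = np.random.default_rng(seed)
    n_helix = max(8, (n_residues - 12) // 2)
    n_strand = 6
    half_sep = 6.5 + rng.uniform(-0.3, 0.3)

    segments = [
        (_place_segment(build_backbone_segment(n_helix, -57.0, -47.0),
                        target_axis=(0, 1, 0),
                        target_center=(-half_sep, 0.0, 1.0)), 1),
        (_place_segment(build_backbone_segment(n_helix, -57.0, -47.0),
                        target_axis=(0, -1, 0),
                        target_center=(half_sep, 0.0, 1.0)), 101),
        (_place_segment(build_backbone_segment(n_strand, -139.0, 135.0),
                        target_axis=(1, 0, 0),
                        target_center=(0.0, -2.4, -5.5)), 201),
        (_place_segment(build_backbone_segment(n_strand, -139.0, 135.0),
                        target_axis=(-1, 0, 0),
                        target_center=(0.0, 2.4, -5.5)), 301),
    ]
    if occluded:
        number = OCCLUDER_START
        for z in (-0.5, 2.6):
            for y in (-3.0, 0.0, 3.0):
                segments.append(
                    (_place_segment(
                        build_backbone_segment(n_strand, -139.0, 135.0),
                        target_axis=(1, 0, 0), target_center=(0.0, y, z)),
                     number))
                number += n_strand + 2

    residues = []
    for segment, start in segments:
        number = start
        for bb in segment:
            res = Residue(name3="ALA", chain="A", number=number)
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                res.atoms[name] = Atom(name, el, bb[name])
            res = build_side_chain(res, "ALA", [])
            residues.append(res)
            number += 1
    return Structure(residues=residues)


def pocket_center(scaffold: Structure) -> np.ndarray:
    """The geometric pocket focus of the toy scaffold."""
    return np.array([0.0, 0.0, 0.5])


def pocket_positions(scaffold: Structure, max_dist: float = 12.0) -> list:
    """Residue keys of pocket-lining residues (CB pointing toward the center).

    Occluder segments of negative-control scaffolds are not pocket-lining
    and are excluded.
    """
    center = pocket_center(scaffold)
    out = []
    for res in scaffold.residues:
        if not res.has("CA", "CB") or res.number >= OCCLUDER_START:
            continue
        ca, cb = res.coord("CA"), res.coord("CB")
        to_center = center - ca
        dist = np.linalg.norm(to_center)
        if dist > max_dist:
            continue
        cb_dir = cb - ca
        cosang = np.dot(to_center, cb_dir) / (
            np.linalg.norm(to_center) * np.linalg.norm(cb_dir))
        if cosang > 0.5:
            out.append(res.key)
    return out


# ---------------------------------------------------------------------------
# planted sites
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    position: tuple
    residue_type: str
    chi: tuple
    triple: tuple          # protein atom-name triple realising the block


@dataclass
class PlantedSite:
    """A scaffold with a theozyme planted at known ground truth."""

    scaffold: Structure
    theozyme: Theozyme
    ligand: LigandTopology
    truth: list                    # PlantedTruth per block, in order
    ligand_coords: dict            # atom name -> xyz of the planted pose
    positions: list                # posfile selectors covering the site

    def truth_residue(self, block_index: int) -> Residue:
        t = self.truth[block_index - 1]
        res = self.scaffold.find(*t.position)
        return build_side_chain(res, t.residue_type, list(t.chi))


class PlantingError(RuntimeError):
    pass


def _x0_tuple(block, fill: dict | None = None) -> ParamTuple:
    """The block's ideal values as a full six-parameter tuple.

    Undefined parameters are taken from ``fill`` (required for such blocks).
    """
    fill = fill or {}
    vals = {}
    for name in geometry.PARAM_NAMES:
        if name in block.params:
            vals[name] = block.params[name].x0
        elif name in fill:
            vals[name] = fill[name]
        else:
            raise PlantingError(f"no value for undefined parameter {name}")
    return ParamTuple(**vals)


def _ligand_clash_free(lig_xyz: np.ndarray, lig_radii, bb_coords, bb_radii,
                       clash_factor: float) -> bool:
    diff = lig_xyz[:, None, :] - bb_coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    lim = clash_factor * (lig_radii[:, None] + bb_radii[None, :])
    return bool(np.all(dist >= lim))


def _chi_grid(name3: str):
    import itertools
    topo = RESIDUE_TOPOLOGIES[name3]
    return list(itertools.product(CHI_SAMPLES, repeat=topo.n_chi))


def _residue_triple_geometry(res: Residue, names) -> tuple:
    a, b, c = (res.coord(n) for n in names)
    return (float(np.linalg.norm(a - b)), float(np.linalg.norm(b - c)),
            float(geometry.angle(a, b, c)))


def _transform_residue_onto_triple(res: Residue, names, target: np.ndarray
                                   ) -> Residue:
    moving = np.stack([res.coord(n) for n in names])
    R, t = geometry.superpose_transform(target, moving)
    out = res.copy()
    for atom in out.atoms.values():
        atom.xyz = R @ atom.xyz + t
    return out


def plant_site(scaffold: Structure, theozyme: Theozyme | None = None,
               seed: int = 0, ligand: LigandTopology | None = None,
               clash_factor: float = 0.7, max_ca_shift: float = 3.5,
               max_tries: int = 200) -> PlantedSite:
    """Plant the theozyme into the scaffold with exact ground truth.

    Construction is inverse: a first-block rotamer from the reduced library
    places the ligand at the block's ideal values; for each further block a
    residue is built with library chi angles and rigidly moved so that its
    constrained atom triple realises the block's ideal values against the
    planted ligand exactly, carrying its backbone with it (the scaffold
    backbone at that position is replaced).  All defined parameters of every
    block therefore measure exactly x0 at the truth geometry.
    """
    if theozyme is None or ligand is None:
        tz, lig = make_theozyme_tim()
        theozyme = theozyme or tz
        ligand = ligand or lig
    theozyme.validate()
    rng = np.random.default_rng(seed)
    center = pocket_center(scaffold)
    candidates = pocket_positions(scaffold)
    if len(candidates) < len(theozyme.blocks):
        raise PlantingError("scaffold pocket offers too few facing positions")

    conf = ligand.conformers[0]
    lig_names = ligand.atom_names()
    lig_local = np.stack([np.asarray(conf[n], float) for n in lig_names])
    lig_radii = np.array([ligand.atom(n).radius for n in lig_names])

    block1 = theozyme.blocks[0]
    anchor1 = resolve_atom_triples(block1.ligand_map, ligand)[0]
    anchor_local = np.stack([np.asarray(conf[n], float) for n in anchor1])
    b12 = ligand.internal_bond(anchor1[0], anchor1[1])
    b23 = ligand.internal_bond(anchor1[1], anchor1[2])
    a123 = ligand.internal_angle(*anchor1)
    x0_1 = _x0_tuple(block1)

    order = list(candidates)
    rng.shuffle(order)
    scaffold = scaffold.copy()
    bb_coords, bb_radii = scaffold_backbone_arrays(scaffold)

    for tries, p1 in enumerate(order * (max_tries // len(order) + 1)):
        if tries >= max_tries:
            break
        res1_type = rng.choice(block1.protein_map.allowed_residues)
        chi1 = _chi_grid(res1_type)
        chi1 = chi1[rng.integers(len(chi1))]
        base1 = scaffold.find(*p1)
        built1 = build_side_chain(base1, res1_type, list(chi1))
        triples1 = resolve_atom_triples(
            block1.protein_map, RESIDUE_TOPOLOGIES[res1_type])
        prot_triple_names = triples1[rng.integers(len(triples1))]
        prot_triple = np.stack([built1.coord(n) for n in prot_triple_names])
        # ligand anchors built from the protein side: swap partner roles
        anchors = geometry.build_partner2_triple(
            prot_triple, x0_1.swapped(), b12, b23, a123)
        o_w, R_w = geometry.frame_from_triple(anchors)
        o_l, R_l = geometry.frame_from_triple(anchor_local)
        R = R_w @ R_l.T
        lig_xyz = (lig_local - o_l) @ R.T + o_w
        if np.linalg.norm(lig_xyz.mean(axis=0) - center) > 5.0:
            continue
        if not _ligand_clash_free(lig_xyz, lig_radii, bb_coords, bb_radii,
                                  clash_factor):
            continue
        lig_coords = {n: lig_xyz[i] for i, n in enumerate(lig_names)}
        truth = [PlantedTruth(p1, res1_type, tuple(chi1),
                              tuple(prot_triple_names))]
        used = {p1}
        work = scaffold.copy()
        ok = True
        for bi, block in enumerate(theozyme.blocks[1:], start=2):
            placed = _plant_block(work, block, lig_coords, ligand, used,
                                  candidates, rng, lig_xyz, lig_radii,
                                  clash_factor, max_ca_shift)
            if placed is None:
                ok = False
                break
            truth.append(placed)
            used.add(placed.position)
        if not ok:
            continue
        posfile = sorted(set(candidates) | used)
        return PlantedSite(scaffold=work, theozyme=theozyme, ligand=ligand,
                           truth=truth, ligand_coords=lig_coords,
                           positions=[(c, n) for c, n in posfile])
    raise PlantingError(
        "no clash-free planted arrangement found; try a larger pocket")


def _fill_tuples(block) -> tuple:
    """Full six-parameter tuples for a block, as stacked arrays over fills.

    Fully specified blocks give one tuple (all x0); blocks with undefined
    torsions sweep them on a 30-degree grid.
    """
    missing = [n for n in geometry.PARAM_NAMES if n not in block.params]
    base = {n: block.params[n].x0 for n in block.params}
    if not missing:
        return {n: np.array([base[n]]) for n in geometry.PARAM_NAMES}
    grid = np.arange(-180.0, 180.0, 30.0)
    mesh = np.meshgrid(*([grid] * len(missing)), indexing="ij")
    n_fill = mesh[0].size
    out = {n: np.full(n_fill, base[n]) for n in base}
    for name, m in zip(missing, mesh):
        out[name] = m.ravel()
    return out


def _plant_block(scaffold: Structure, block, lig_coords, ligand, used,
                 candidates, rng, lig_xyz, lig_radii, clash_factor,
                 max_ca_shift):
    """Place one non-first block's residue exactly; returns PlantedTruth.

    For every candidate position, library chi combination and atom-triple
    choice, the target protein triple is built from the planted ligand at
    the block's ideal values (undefined torsions swept on a grid), and the
    frame-aligned rigid move of the built residue onto it is evaluated for
    backbone displacement and ligand clearance, vectorised over the sweep.
    """
    fills = _fill_tuples(block)
    lig_triples = resolve_atom_triples(block.ligand_map, ligand)
    best = None
    for p in candidates:
        if p in used:
            continue
        base = scaffold.find(*p)
        orig_ca = base.coord("CA")
        for res_type in block.protein_map.allowed_residues:
            topo = RESIDUE_TOPOLOGIES[res_type]
            prot_triples = resolve_atom_triples(block.protein_map, topo)
            for chis in _chi_grid(res_type):
                built = build_side_chain(base, res_type, list(chis))
                bb_names = [n for n in ("N", "CA", "C", "O", "CB")
                            if n in built.atoms]
                bb_xyz = np.stack([built.coord(n) for n in bb_names])
                bb_radii = np.array([built.atoms[n].radius for n in bb_names])
                for names in prot_triples:
                    tb12, tb23, ta123 = _residue_triple_geometry(built, names)
                    built_triple = np.stack([built.coord(n) for n in names])
                    o_b, R_b = geometry.frame_from_triple(built_triple)
                    for lnames in lig_triples:
                        l_triple = np.stack(
                            [np.asarray(lig_coords[n], float) for n in lnames])
                        a1, a2, a3 = l_triple
                        # target triples for all fills at once (F, 3, 3)
                        t1 = geometry.place_atom(
                            a3, a2, a1, fills["distanceAB"], fills["angle_A"],
                            fills["torsion_A"])
                        t2 = geometry.place_atom(
                            a2, a1, t1, tb12, fills["angle_B"],
                            fills["torsion_AB"])
                        t3 = geometry.place_atom(
                            a1, t1, t2, tb23, ta123, fills["torsion_B"])
                        targets = np.stack([t1, t2, t3], axis=-2)
                        from .matcher import _frames
                        o_t, R_t = _frames(targets)
                        R_all = R_t @ R_b.T                      # (F, 3, 3)
                        moved_ca = (R_all @ (built.coord("CA") - o_b)) + o_t
                        shifts = np.linalg.norm(moved_ca - orig_ca, axis=-1)
                        cand = np.nonzero(shifts <= max_ca_shift)[0]
                        if cand.size == 0:
                            continue
                        moved_bb = np.einsum(
                            "fij,aj->fai", R_all[cand], bb_xyz - o_b) \
                            + o_t[cand][:, None, :]              # (F', 5, 3)
                        diff = lig_xyz[None, :, None, :] \
                            - moved_bb[:, None, :, :]
                        dist = np.sqrt(np.sum(diff * diff, axis=-1))
                        lim = clash_factor * (lig_radii[None, :, None]
                                              + bb_radii[None, None, :])
                        clear = np.all(dist >= lim, axis=(1, 2))
                        ok = cand[clear]
                        if ok.size == 0:
                            continue
                        j = ok[np.argmin(shifts[ok])]
                        if best is None or shifts[j] < best[0]:
                            best = (float(shifts[j]), p, res_type, chis,
                                    names, R_all[j], o_b, o_t[j])
    if best is None:
        return None
    _, p, res_type, chis, names, R, o_b, o_t = best
    res = scaffold.find(*p)
    moved = build_side_chain(res, res_type, list(chis))
    for atom in moved.atoms.values():
        atom.xyz = R @ (atom.xyz - o_b) + o_t
    res.name3 = moved.name3
    res.atoms = moved.atoms
    scaffold.reindex()
    return PlantedTruth(p, res_type, tuple(chis), tuple(names))


def _bb_clear_of_ligand(res: Residue, lig_xyz, lig_radii, clash_factor) -> bool:
    bb = np.stack([res.coord(n) for n in ("N", "CA", "C", "O", "CB")
                   if n in res.atoms])
    radii = np.array([res.atoms[n].radius for n in ("N", "CA", "C", "O", "CB")
                      if n in res.atoms])
    diff = lig_xyz[:, None, :] - bb[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    lim = clash_factor * (lig_radii[:, None] + radii[None, :])
    return bool(np.all(dist >= lim))


# ---------------------------------------------------------------------------
# worked directory
# ---------------------------------------------------------------------------

def write_fixture_dir(out_dir, seed: int = 0, planted: bool = True) -> dict:
    """Emit a complete worked input set: scaffold, params, cstfile, posfile."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    theozyme, ligand = make_theozyme_tim()
    scaffold = make_toy_scaffold(seed=seed)
    if planted:
        site = plant_site(scaffold, theozyme, seed=seed, ligand=ligand)
        scaffold = site.scaffold
        positions = site.positions
    else:
        positions = [(c, n) for c, n in pocket_positions(scaffold)]
    write_pdb(scaffold, out / "scaffold.pdb")
    (out / "ligand.params").write_text(write_ligand_params(ligand))
    (out / "theozyme.cst").write_text(write_cstfile(theozyme))
    (out / "positions.pos").write_text(
        " ".join(f"{c}{n}" for c, n in positions) + "\n")
    return {"scaffold": out / "scaffold.pdb", "params": out / "ligand.params",
            "cst": out / "theozyme.cst", "pos": out / "positions.pos"}
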