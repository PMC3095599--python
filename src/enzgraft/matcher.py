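"""Grafting a theozyme into scaffolds: classic and secondary matching.

Classic matching builds side-chain rotamers at every candidate scaffold
position and, for each rotamer, places the ligand at every sampled value
combination of the six constraint parameters.  Collision-free placements are
"hits": a rotamer plus a 6D ligand pose (3 Euclidean + 3 Euler coordinates).
Secondary matching re-evaluates candidate rotamers against previously
generated ligand placements (or partner rotamers), checking only the
parameters the block defines.  Hits from all N interactions are binned on the
6D coordinate; every bin holding at least one hit per interaction yields
matches — successful grafts.

Hit generation and hashing are vectorised: hits live in per-rotamer array
batches and are materialised as ``Hit`` objects only where a caller (or a
qualifying bin) needs them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry
from .chem import CHI_SAMPLES, EX_DELTA, RESIDUE_TOPOLOGIES
from .cst import ConstraintBlock, Theozyme, enumerate_samples, resolve_atom_triples
from .geometry import PARAM_NAMES, Pose6D
from .structure import (BACKBONE_ATOMS, LigandTopology, Residue, Structure,
                        build_side_chain_batch, measure_chis)

log = logging.getLogger(__name__)


@dataclass
class MatchConfig:
    """Matcher settings.

    Bin widths default to 1.0 A / 15 degrees; there is no cross-bin neighbour
    merging, so hits straddling a bin boundary do not combine.  ``clash_factor``
    scales the summed vdW radii in the backbone collision test.
    """

    euclid_bin: float = 1.0
    euler_bin: float = 15.0
    clash_factor: float = 0.7
    ex1: bool = False
    ex2: bool = False
    use_input_sc: bool = False
    max_per_bin: int = 5
    max_hit_expand: int = 8        # hits per interaction considered per bin
    ligand_frame: tuple = ()       # frame atom names; default: first block's ligand triple

    def __post_init__(self):
        if self.euclid_bin <= 0 or self.euler_bin <= 0:
            raise ValueError("bin widths must be positive")
        if not 0 < self.clash_factor <= 1:
            raise ValueError("clash_factor must be in (0, 1]")


@dataclass
class Rotamer:
    """A discrete side-chain conformation built at one scaffold position."""

    position: tuple                # (chain, number)
    residue_type: str
    chi: tuple
    coords: dict                   # atom name -> xyz (backbone + side chain)
    template: Residue = None       # scaffold residue supplying chain/number
    _residue: Residue = field(default=None, repr=False, compare=False)

    @property
    def atoms(self) -> dict:
        return self.coords

    def coord(self, name: str) -> np.ndarray:
        return self.coords[name]

    @property
    def residue(self) -> Residue:
        """The rotamer as a full Residue (built lazily)."""
        if self._residue is None:
            from .structure import residue_from_coords
            self._residue = residue_from_coords(
                self.template, self.residue_type, self.coords)
        return self._residue


@dataclass
class Hit:
    """One collision-free ligand placement for one theozyme interaction."""

    interaction_index: int
    rotamer: Rotamer
    pose: Pose6D
    ligand_conformer: int
    lig_names: tuple               # ligand atom names, shared ordering
    lig_xyz: np.ndarray            # (n_atoms, 3) placed coordinates
    score: float = 0.0             # realised restraint score of this block

    @property
    def ligand_coords(self) -> dict:
        return dict(zip(self.lig_names, self.lig_xyz))


@dataclass
class HitBatch:
    """Hits sharing one rotamer and conformer, stored as arrays."""

    interaction_index: int
    rotamer: Rotamer
    conformer: int
    lig_names: tuple
    placed: np.ndarray             # (S, n_atoms, 3)
    poses: np.ndarray              # (S, 6): tx ty tz e1 e2 e3
    keys: np.ndarray               # (S, 6) int bin indices
    scores: np.ndarray             # (S,)

    def __len__(self) -> int:
        return self.placed.shape[0]

    def hit(self, row: int) -> Hit:
        return Hit(
            interaction_index=self.interaction_index, rotamer=self.rotamer,
            pose=Pose6D(*map(float, self.poses[row])),
            ligand_conformer=self.conformer, lig_names=self.lig_names,
            lig_xyz=self.placed[row], score=float(self.scores[row]))

    def to_hits(self) -> list:
        return [self.hit(i) for i in range(len(self))]


BinKey = tuple


@dataclass
class MatchRecord:
    scaffold_id: str
    bin: BinKey
    hits: tuple                    # one Hit per interaction, index order
    match_score: float

    @property
    def positions(self) -> tuple:
        return tuple(h.rotamer.position for h in self.hits)

    @property
    def residue_types(self) -> tuple:
        return tuple(h.rotamer.residue_type for h in self.hits)


# ---------------------------------------------------------------------------
# rotamers
# ---------------------------------------------------------------------------

def _chi_samples(n_chi: int, ex1: bool, ex2: bool) -> list:
    """The sample grid of the reduced rotamer library.

    Three canonical samples per chi; -ex1/-ex2 add +-EX_DELTA about each
    canonical chi1/chi2 value, tripling that chi's samples.
    """
    per_chi = []
    for k in range(1, n_chi + 1):
        base = list(CHI_SAMPLES)
        if (k == 1 and ex1) or (k == 2 and ex2):
            expanded = []
            for b in base:
                expanded.extend([b - EX_DELTA, b, b + EX_DELTA])
            base = expanded
        per_chi.append(base)
    return [tuple(c) for c in itertools.product(*per_chi)] if per_chi else [()]


def build_rotamers(scaffold: Structure, position: tuple, residue_types,
                   ex1: bool = False, ex2: bool = False,
                   use_input: bool = False) -> list:
    """Rotamers of the given residue types at one scaffold position.

    Atoms are constructed off the existing backbone by internal coordinates.
    Glycine contributes no rotamers (no side chain to graft).
    """
    res = scaffold.find(*position)
    if not res.has("N", "CA", "C"):
        raise ValueError(f"position {position} lacks backbone N/CA/C")
    out = []
    for name3 in residue_types:
        if name3 not in RESIDUE_TOPOLOGIES:
            raise ValueError(f"unknown residue type {name3!r}")
        topo = RESIDUE_TOPOLOGIES[name3]
        if not topo.has_cb:
            log.debug("position %s: %s has no side chain, skipped", position, name3)
            continue
        combos = _chi_samples(topo.n_chi, ex1, ex2)
        if use_input and res.name3 == name3 and topo.n_chi > 0:
            try:
                combos = combos + [tuple(measure_chis(res))]
            except Exception:
                pass
        chi_arr = np.asarray(combos, float).reshape(len(combos), topo.n_chi)
        batch = build_side_chain_batch(res, name3, chi_arr)
        for i, chis in enumerate(combos):
            coords = {n: (v[i] if v.ndim == 2 else v)
                      for n, v in batch.items()}
            out.append(Rotamer(position, name3, tuple(chis), coords, res))
    return out


# ---------------------------------------------------------------------------
# vectorised helpers
# ---------------------------------------------------------------------------

def _frames(triples: np.ndarray):
    """Orthonormal frames for a batch of atom triples, shape (..., 3, 3)."""
    a1 = triples[..., 0, :]
    a2 = triples[..., 1, :]
    a3 = triples[..., 2, :]
    e1 = a2 - a1
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    u = a3 - a1
    u = u - np.sum(u * e1, axis=-1, keepdims=True) * e1
    e2 = u / np.linalg.norm(u, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return a1, np.stack([e1, e2, e3], axis=-1)


def _pose_array_from_triples(triples: np.ndarray) -> np.ndarray:
    """(S, 6) pose rows (tx ty tz e1 e2 e3) for a batch of frame triples."""
    import warnings
    origin, R = _frames(triples)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        eulers = Rotation.from_matrix(R).as_euler("zxz", degrees=True) % 360.0
    return np.concatenate([np.atleast_2d(origin), np.atleast_2d(eulers)], axis=-1)


def _keys_from_poses(poses: np.ndarray, cfg: MatchConfig) -> np.ndarray:
    k = np.empty(poses.shape, dtype=np.int64)
    k[..., :3] = np.floor(poses[..., :3] / cfg.euclid_bin)
    k[..., 3:] = np.floor((poses[..., 3:] % 360.0) / cfg.euler_bin)
    return k


def _measure_batch(t1: np.ndarray, t2: np.ndarray) -> dict:
    """The six parameters between triple batches t1, t2 of shape (..., 3, 3)."""
    a1, a2, a3 = t1[..., 0, :], t1[..., 1, :], t1[..., 2, :]
    b1, b2, b3 = t2[..., 0, :], t2[..., 1, :], t2[..., 2, :]
    return {
        "distanceAB": geometry.distance(a1, b1),
        "angle_A": geometry.angle(a2, a1, b1),
        "angle_B": geometry.angle(a1, b1, b2),
        "torsion_A": geometry.dihedral(a3, a2, a1, b1),
        "torsion_AB": geometry.dihedral(a2, a1, b1, b2),
        "torsion_B": geometry.dihedral(a1, b1, b2, b3),
    }


def _penalties_batch(block: ConstraintBlock, measured: dict) -> np.ndarray:
    total = 0.0
    for name, p in block.params.items():
        total = total + geometry.penalty(measured[name], p)
    return np.asarray(total, float)


def _satisfied_batch(block: ConstraintBlock, measured: dict) -> np.ndarray:
    """Boolean mask: every defined parameter inside its flat bottom."""
    ok = True
    for name, p in block.params.items():
        if name == "distanceAB":
            delta = np.abs(measured[name] - p.x0)
        else:
            delta = geometry.periodic_delta(measured[name], p.x0, p.fourth)
        ok = ok & (delta <= p.xtol)
    return np.asarray(ok, bool)


def scaffold_backbone_arrays(scaffold: Structure, skip_position=None):
    """Coordinates and radii of backbone (N/CA/C/O/CB) atoms for clash tests."""
    coords, radii = [], []
    for res in scaffold.residues:
        if skip_position is not None and res.key == skip_position:
            pass  # own backbone still collides with the ligand
        for name in (*BACKBONE_ATOMS, "CB"):
            if name in res.atoms:
                coords.append(res.atoms[name].xyz)
                radii.append(res.atoms[name].radius)
    return np.asarray(coords), np.asarray(radii)


def ligand_frame_atoms(theozyme: Theozyme, ligand: LigandTopology,
                       cfg: MatchConfig) -> tuple:
    if cfg.ligand_frame:
        return tuple(cfg.ligand_frame)
    lmap = theozyme.blocks[0].ligand_map
    if lmap.mode == "by_name":
        return tuple(lmap.names)
    triples = resolve_atom_triples(lmap, ligand)
    if not triples:
        raise ValueError("cannot derive a ligand frame from the first block")
    return triples[0]


def _ligand_anchor_triples(block: ConstraintBlock, ligand: LigandTopology):
    return resolve_atom_triples(block.ligand_map, ligand)


def _protein_triples(block: ConstraintBlock, name3: str):
    topo = RESIDUE_TOPOLOGIES[name3]
    try:
        return resolve_atom_triples(block.protein_map, topo)
    except KeyError:
        return []


# ---------------------------------------------------------------------------
# classic matching
# ---------------------------------------------------------------------------

def _classic_batches(scaffold: Structure, block: ConstraintBlock,
                     interaction_index: int, positions,
                     ligand: LigandTopology, cfg: MatchConfig,
                     frame_atoms: tuple,
                     diagnostics: dict | None = None) -> list:
    block.validate()
    if any(name not in block.params for name in PARAM_NAMES):
        raise ValueError("classic matching requires all six parameters")
    ligand_is_1 = block.map1.is_ligand

    samples = {name: np.asarray(enumerate_samples(block.params[name]))
               for name in PARAM_NAMES}
    grids = np.meshgrid(*(samples[n] for n in PARAM_NAMES), indexing="ij")
    flat = {n: g.ravel() for n, g in zip(PARAM_NAMES, grids)}

    # parameters as seen from the protein triple acting as builder
    if ligand_is_1:
        d = flat["distanceAB"]; aA = flat["angle_B"]; tA = flat["torsion_B"]
        aB = flat["angle_A"]; tAB = flat["torsion_AB"]; tB = flat["torsion_A"]
    else:
        d = flat["distanceAB"]; aA = flat["angle_A"]; tA = flat["torsion_A"]
        aB = flat["angle_B"]; tAB = flat["torsion_AB"]; tB = flat["torsion_B"]

    sample_scores = _penalties_batch(block, {n: flat[n] for n in PARAM_NAMES})

    bb_coords, bb_radii = scaffold_backbone_arrays(scaffold)
    conf_id = 0
    conf = ligand.conformers[conf_id]
    lig_names = tuple(ligand.atom_names())
    lig_xyz = np.stack([np.asarray(conf[n], float) for n in lig_names])
    lig_radii = np.array([ligand.atom(n).radius for n in lig_names])
    frame_idx = [lig_names.index(n) for n in frame_atoms]
    clash_lim2 = (cfg.clash_factor
                  * (lig_radii[None, :, None] + bb_radii[None, None, :])) ** 2

    # collect (rotamer, protein triple) groups so placement, clash test and
    # pose extraction run batched over all of them at once
    groups: list = []
    triple_rows: list = []
    for position in positions:
        rotamers = build_rotamers(
            scaffold, position, block.protein_map.allowed_residues,
            ex1=cfg.ex1, ex2=cfg.ex2, use_input=cfg.use_input_sc)
        for rot in rotamers:
            for prot_names in _protein_triples(block, rot.residue_type):
                groups.append(rot)
                triple_rows.append(np.stack(
                    [rot.coord(n) for n in prot_names]))

    batches = []
    rejected = 0
    if not groups:
        if diagnostics is not None:
            diagnostics[f"classic_{interaction_index}_rejected"] = 0
            diagnostics[f"classic_{interaction_index}_hits"] = 0
        return batches
    triples = np.stack(triple_rows)                         # (G, 3, 3)
    n_groups = triples.shape[0]

    for anchor_names in _ligand_anchor_triples(block, ligand):
        anchor_local = np.stack(
            [np.asarray(conf[n], float) for n in anchor_names])
        b12 = ligand.internal_bond(anchor_names[0], anchor_names[1])
        b23 = ligand.internal_bond(anchor_names[1], anchor_names[2])
        a123 = ligand.internal_angle(*anchor_names)
        p1 = triples[:, None, 0, :]
        p2 = triples[:, None, 1, :]
        p3 = triples[:, None, 2, :]
        b1 = geometry.place_atom(p3, p2, p1, d, aA, tA)     # (G, S, 3)
        b2 = geometry.place_atom(p2, p1, b1, b12, aB, tAB)
        b3 = geometry.place_atom(p1, b1, b2, b23, a123, tB)
        anchors = np.stack([b1, b2, b3], axis=-2)           # (G, S, 3, 3)
        o_w, R_w = _frames(anchors)
        o_l, R_l = _frames(anchor_local[None])
        R = R_w @ np.swapaxes(R_l, -1, -2)
        placed = np.einsum("gsij,aj->gsai", R, lig_xyz - o_l[0]) \
            + o_w[..., None, :]                             # (G, S, n_atoms, 3)
        # backbone collision test: per ligand atom, squared distances to all
        # backbone atoms via |a-b|^2 = |a|^2 + |b|^2 - 2 a.b (BLAS matmul)
        n_s = placed.shape[1]
        n_rows = n_groups * n_s
        bb32 = bb_coords.astype(np.float32)
        bb2 = np.sum(bb32 * bb32, axis=1)
        clash_flat = np.zeros(n_rows, bool)
        row_chunk = max(1, int(2e7 // max(1, bb32.shape[0])))
        for a in range(lig_xyz.shape[0]):
            lim2_a = clash_lim2[0, a].astype(np.float32)
            pts = placed[:, :, a, :].reshape(n_rows, 3).astype(np.float32)
            p2 = np.sum(pts * pts, axis=1)
            for lo in range(0, n_rows, row_chunk):
                hi = min(n_rows, lo + row_chunk)
                d2 = (p2[lo:hi, None] + bb2[None, :]
                      - 2.0 * (pts[lo:hi] @ bb32.T))
                clash_flat[lo:hi] |= np.any(d2 < lim2_a[None, :], axis=1)
        keep_mask = ~clash_flat.reshape(n_groups, n_s)
        rejected += int(np.count_nonzero(clash_flat))
        g_idx, s_idx = np.nonzero(keep_mask)
        if g_idx.size == 0:
            continue
        kept = placed[g_idx, s_idx]                         # (K, n_atoms, 3)
        poses = _pose_array_from_triples(kept[:, frame_idx, :])
        keys = _keys_from_poses(poses, cfg)
        scores = sample_scores[s_idx]
        bounds = np.searchsorted(g_idx, np.arange(n_groups + 1))
        for g in range(n_groups):
            lo, hi = bounds[g], bounds[g + 1]
            if lo == hi:
                continue
            batches.append(HitBatch(
                interaction_index=interaction_index, rotamer=groups[g],
                conformer=conf_id, lig_names=lig_names,
                placed=kept[lo:hi], poses=poses[lo:hi],
                keys=keys[lo:hi], scores=scores[lo:hi]))
    if diagnostics is not None:
        diagnostics[f"classic_{interaction_index}_rejected"] = rejected
        diagnostics[f"classic_{interaction_index}_hits"] = sum(
            len(b) for b in batches)
    return batches


def classic_match_interaction(scaffold: Structure, block: ConstraintBlock,
                              interaction_index: int, positions,
                              ligand: LigandTopology, cfg: MatchConfig,
                              frame_atoms: tuple,
                              diagnostics: dict | None = None) -> list:
    """Hits from building the ligand outward from every rotamer and sample.

    For every rotamer at every position and every Cartesian combination of
    the six parameters' sample values, the ligand anchor triple is built by
    internal-coordinate placement, the full conformer rigidly mapped onto it,
    and placements clashing with the scaffold backbone are discarded.
    """
    batches = _classic_batches(scaffold, block, interaction_index, positions,
                               ligand, cfg, frame_atoms, diagnostics)
    return [h for b in batches for h in b.to_hits()]


# ---------------------------------------------------------------------------
# secondary matching
# ---------------------------------------------------------------------------

def _unique_placements(batches: list):
    """Deduplicated prior ligand placements across batches.

    Returns (placed (P, n_atoms, 3), poses (P, 6), keys (P, 6),
    source list of (batch, row)).  Placements are identical when their poses
    agree to 1e-3.
    """
    all_placed = np.concatenate([b.placed for b in batches])
    all_poses = np.concatenate([b.poses for b in batches])
    all_keys = np.concatenate([b.keys for b in batches])
    sources = [(b, i) for b in batches for i in range(len(b))]
    _, idx = np.unique(np.round(all_poses, 3), axis=0, return_index=True)
    idx = np.sort(idx)
    return (all_placed[idx], all_poses[idx], all_keys[idx],
            [sources[i] for i in idx])


def _secondary_batches(scaffold: Structure, block: ConstraintBlock,
                       interaction_index: int, prior_batches, positions,
                       ligand: LigandTopology, cfg: MatchConfig) -> list:
    block.validate()
    if not prior_batches or all(len(b) == 0 for b in prior_batches):
        log.warning("secondary matching for interaction %d has no prior hits",
                    interaction_index)
        return []
    ligand_mediated = any(m.is_ligand for m in (block.map1, block.map2))
    if not ligand_mediated:
        hits = _secondary_sidechain_sidechain(
            scaffold, block, interaction_index,
            [h for b in prior_batches for h in b.to_hits()], positions, cfg)
        return [_batch_from_hits(hits)] if hits else []

    placed, poses, keys, _ = _unique_placements(prior_batches)
    ligand_is_1 = block.map1.is_ligand
    name_order = list(prior_batches[0].lig_names)
    lig_triples = []
    for names in _ligand_anchor_triples(block, ligand):
        idx = [name_order.index(n) for n in names]
        lig_triples.append(placed[:, idx, :])               # (P, 3, 3)
    dist_param = block.params.get("distanceAB")

    batches = []
    for position in positions:
        rotamers = build_rotamers(
            scaffold, position, block.protein_map.allowed_residues,
            ex1=cfg.ex1, ex2=cfg.ex2, use_input=cfg.use_input_sc)
        if not rotamers:
            continue
        # position-level prefilter: the constrained ligand anchor must come
        # within reach of a side chain rooted at this CA
        if dist_param is not None:
            ca = scaffold.find(*position).coord("CA")
            reach = 12.0 + dist_param.x0 + dist_param.xtol
            near = np.zeros(placed.shape[0], bool)
            for ltrip in lig_triples:
                near |= (np.linalg.norm(ltrip[:, 0, :] - ca, axis=-1) <= reach)
            pos_sel = np.nonzero(near)[0]
            if pos_sel.size == 0:
                continue
            pos_triples = [lt[pos_sel] for lt in lig_triples]
        else:
            pos_sel = np.arange(placed.shape[0])
            pos_triples = lig_triples
        for rot in rotamers:
            best_ok = np.zeros(pos_sel.size, bool)
            best_scores = np.full(pos_sel.size, np.inf)
            for prot_names in _protein_triples(block, rot.residue_type):
                prot = np.stack([rot.coord(n) for n in prot_names])
                for ltrip in pos_triples:
                    # cheap prefilter: a placement whose anchor atom violates
                    # the distance flat bottom can never be accepted
                    if dist_param is not None:
                        d = np.linalg.norm(ltrip[:, 0, :] - prot[0], axis=-1)
                        sel = np.nonzero(
                            np.abs(d - dist_param.x0) <= dist_param.xtol)[0]
                    else:
                        sel = np.arange(pos_sel.size)
                    if sel.size == 0:
                        continue
                    lt = ltrip[sel]
                    prot_b = np.broadcast_to(prot, lt.shape)
                    if ligand_is_1:
                        measured = _measure_batch(lt, prot_b)
                    else:
                        measured = _measure_batch(prot_b, lt)
                    ok = _satisfied_batch(block, measured)
                    scores = _penalties_batch(block, measured)
                    best_ok[sel] |= ok
                    best_scores[sel] = np.minimum(best_scores[sel], scores)
            rows = pos_sel[np.nonzero(best_ok)[0]]
            if rows.size == 0:
                continue
            batches.append(HitBatch(
                interaction_index=interaction_index, rotamer=rot,
                conformer=prior_batches[0].conformer,
                lig_names=tuple(name_order),
                placed=placed[rows], poses=poses[rows], keys=keys[rows],
                scores=best_scores[np.nonzero(best_ok)[0]]))
    return batches


def _batch_from_hits(hits: list) -> HitBatch:
    h0 = hits[0]
    return HitBatch(
        interaction_index=h0.interaction_index, rotamer=h0.rotamer,
        conformer=h0.ligand_conformer, lig_names=h0.lig_names,
        placed=np.stack([h.lig_xyz for h in hits]),
        poses=np.stack([h.pose.as_array() for h in hits]),
        keys=np.zeros((len(hits), 6), np.int64),
        scores=np.array([h.score for h in hits]))


def secondary_match_interaction(scaffold: Structure, block: ConstraintBlock,
                                interaction_index: int, prior_hits,
                                positions, ligand: LigandTopology,
                                cfg: MatchConfig) -> list:
    """Hits from evaluating rotamers against previously generated placements.

    Only the block's defined parameters are evaluated; parameters absent from
    the block are ignored.  A (rotamer, prior hit) pair is accepted when
    every defined parameter lies within tolerance of some periodic copy of
    its ideal value; the 6D coordinate is copied from the prior hit.
    """
    if not prior_hits:
        log.warning("secondary matching for interaction %d has no prior hits",
                    interaction_index)
        return []
    prior_batches = [_batch_from_hits([h]) for h in prior_hits]
    batches = _secondary_batches(scaffold, block, interaction_index,
                                 prior_batches, positions, ligand, cfg)
    return [h for b in batches for h in b.to_hits()]


def _secondary_sidechain_sidechain(scaffold, block, interaction_index,
                                   placements, positions, cfg) -> list:
    """Side-chain - side-chain secondary matching.

    Partner 1 of the block is the prior hit's rotamer, partner 2 the
    candidate rotamer; the ligand pose is copied from the prior hit.
    """
    hits = []
    for position in positions:
        rotamers = build_rotamers(
            scaffold, position, block.map2.allowed_residues,
            ex1=cfg.ex1, ex2=cfg.ex2, use_input=cfg.use_input_sc)
        for rot in rotamers:
            coords2 = rot.coords
            triples2 = resolve_atom_triples(
                block.map2, RESIDUE_TOPOLOGIES[rot.residue_type])
            for h in placements:
                if h.rotamer.position == position:
                    continue
                if h.rotamer.residue_type not in block.map1.allowed_residues:
                    continue
                coords1 = h.rotamer.coords
                triples1 = resolve_atom_triples(
                    block.map1, RESIDUE_TOPOLOGIES[h.rotamer.residue_type])
                score, _ = geometry.block_score(
                    block, coords1, coords2, triples1, triples2)
                if score == 0.0:
                    hits.append(Hit(
                        interaction_index=interaction_index, rotamer=rot,
                        pose=h.pose, ligand_conformer=h.ligand_conformer,
                        lig_names=h.lig_names, lig_xyz=h.lig_xyz,
                        score=score))
    return hits


# ---------------------------------------------------------------------------
# hashing and match extraction
# ---------------------------------------------------------------------------

def bin_key(pose: Pose6D, cfg: MatchConfig) -> BinKey:
    """6D bin index: floor(coordinate / width); Euler wrapped to [0, 360) first."""
    tx = int(np.floor(pose.tx / cfg.euclid_bin))
    ty = int(np.floor(pose.ty / cfg.euclid_bin))
    tz = int(np.floor(pose.tz / cfg.euclid_bin))
    e1 = int(np.floor((pose.e1 % 360.0) / cfg.euler_bin))
    e2 = int(np.floor((pose.e2 % 360.0) / cfg.euler_bin))
    e3 = int(np.floor((pose.e3 % 360.0) / cfg.euler_bin))
    return (tx, ty, tz, e1, e2, e3)


def hash_hits(hits, cfg: MatchConfig) -> dict:
    """Group hits by 6D bin, then by interaction index within each bin."""
    table: dict = {}
    for h in hits:
        key = bin_key(h.pose, cfg)
        table.setdefault(key, {}).setdefault(h.interaction_index, []).append(h)
    return table


def _hash_batches(batches: list, cfg: MatchConfig) -> dict:
    """bin key -> interaction -> list of (batch, row)."""
    table: dict = {}
    for b in batches:
        keys = _keys_from_poses(b.poses, cfg)
        b.keys = keys
        for row, key in enumerate(map(tuple, keys.tolist())):
            table.setdefault(key, {}).setdefault(
                b.interaction_index, []).append((b, row))
    return table


def realized_match_score(hits, theozyme: Theozyme,
                         ligand: LigandTopology) -> float:
    """Sum of block scores of the assembled match geometry.

    The assembled match uses the first interaction's ligand placement; every
    hit's rotamer is scored against it (hits from other interactions were
    accepted against their own placement, which shares the bin but need not
    coincide — binning has no cross-bin or intra-bin consistency guarantee,
    so the realised score is what ranks a match).
    """
    lig_coords = hits[0].ligand_coords
    total = 0.0
    for h in hits:
        block = theozyme.blocks[h.interaction_index - 1]
        if not any(m.is_ligand for m in (block.map1, block.map2)):
            continue  # residue-residue blocks are scored pairwise elsewhere
        topo = RESIDUE_TOPOLOGIES[h.rotamer.residue_type]
        t_lig = resolve_atom_triples(block.ligand_map, ligand)
        t_prot = resolve_atom_triples(block.protein_map, topo)
        if block.map1.is_ligand:
            s, _ = geometry.block_score(block, lig_coords, h.rotamer.coords,
                                        t_lig, t_prot)
        else:
            s, _ = geometry.block_score(block, h.rotamer.coords, lig_coords,
                                        t_prot, t_lig)
        total += float(s)
    return total


def find_matches(table: dict, n_interactions: int, cfg: MatchConfig,
                 scaffold_id: str = "scaffold",
                 theozyme: Theozyme | None = None,
                 ligand: LigandTopology | None = None) -> list:
    """Matches from bins holding at least one hit per interaction.

    Per-interaction hits in a bin are ordered by their own restraint score,
    then position, and the Cartesian combinations are emitted best-first up
    to ``max_per_bin``; combinations re-using a scaffold position are
    discarded.  Matches are deduplicated by (positions, residue types, bin).
    When the theozyme and ligand topology are supplied, ``match_score`` is
    the realised restraint score of the assembled geometry (all rotamers
    against the shared ligand placement); otherwise the sum of hit scores.
    """
    if n_interactions < 1:
        raise ValueError("need at least one interaction")
    matches = []
    seen = set()
    for key in sorted(table):
        by_int = table[key]
        if any(i not in by_int for i in range(1, n_interactions + 1)):
            continue
        pools = []
        for i in range(1, n_interactions + 1):
            pool = sorted(by_int[i], key=lambda h: (h.score, h.rotamer.position))
            pools.append(pool[: cfg.max_hit_expand])
        emitted = 0
        for combo in itertools.product(*pools):
            positions = [h.rotamer.position for h in combo]
            if len(set(positions)) != len(positions):
                continue
            dedup = (tuple(positions),
                     tuple(h.rotamer.residue_type for h in combo), key)
            if dedup in seen:
                continue
            seen.add(dedup)
            if theozyme is not None and ligand is not None:
                score = realized_match_score(combo, theozyme, ligand)
            else:
                score = float(sum(h.score for h in combo))
            matches.append(MatchRecord(
                scaffold_id=scaffold_id, bin=key, hits=tuple(combo),
                match_score=score))
            emitted += 1
            if emitted >= cfg.max_per_bin:
                break
    matches.sort(key=lambda m: (m.match_score, m.positions))
    return matches


def _find_matches_batches(table: dict, n_interactions: int, cfg: MatchConfig,
                          scaffold_id: str, theozyme: Theozyme | None = None,
                          ligand: LigandTopology | None = None) -> list:
    """find_matches over the (batch, row) table, materialising qualifying bins."""
    hit_table: dict = {}
    for key, by_int in table.items():
        if any(i not in by_int for i in range(1, n_interactions + 1)):
            continue
        hit_table[key] = {
            i: [b.hit(row) for b, row in pairs]
            for i, pairs in by_int.items()}
    return find_matches(hit_table, n_interactions, cfg, scaffold_id,
                        theozyme, ligand)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def resolve_positions(scaffold: Structure, selectors) -> list:
    """Map posfile selectors to residue keys, skipping absent ones."""
    out = []
    for chain, number in selectors:
        found = [r.key for r in scaffold.residues
                 if r.number == number and (chain is None or r.chain == chain)]
        if not found:
            log.warning("posfile position %s%s absent from scaffold, skipped",
                        chain or "", number)
            continue
        out.extend(k for k in found if k not in out)
    return out


def match_structure(match: MatchRecord, scaffold: Structure,
                    ligand: LigandTopology) -> Structure:
    """The grafted model: scaffold + catalytic side chains + placed ligand."""
    st = scaffold.copy()
    from .structure import CatalyticAnnotation  # local to avoid cycle at import
    st.annotations = []
    for h in match.hits:
        res = st.find(*h.rotamer.position)
        new_res = h.rotamer.residue.copy()
        res.name3 = new_res.name3
        res.atoms = new_res.atoms
        st.annotations.append(CatalyticAnnotation(
            block_index=h.interaction_index, chain=res.chain,
            number=res.number, name3=res.name3))
    lig_res = ligand.placed_residue(match.hits[0].ligand_coords,
                                    chain="X", number=1)
    st.ligands = [lig_res]
    st.reindex()
    return st


def run_matcher(scaffold: Structure, theozyme: Theozyme,
                selectors, ligand: LigandTopology,
                cfg: MatchConfig | None = None,
                scaffold_id: str = "scaffold",
                out_dir=None) -> tuple:
    """The full matching stage.  Returns (matches, diagnostics).

    ``selectors`` are posfile residue selectors.  When ``out_dir`` is given,
    one PDB per match is written (grafted side chains, placed ligand,
    catalytic annotation remarks) plus a tab-separated summary.
    """
    cfg = cfg or MatchConfig()
    theozyme.validate()
    ligand.validate()
    if theozyme.blocks[0].algorithm != "classic":
        raise ValueError(
            "classic matching must be used for the first theozyme interaction")
    positions = resolve_positions(scaffold, selectors)
    diagnostics: dict = {"positions": len(positions)}
    frame = ligand_frame_atoms(theozyme, ligand, cfg)

    all_batches: list = []
    prior: list = []
    for i, block in enumerate(theozyme.blocks, start=1):
        if block.algorithm == "classic":
            batches = _classic_batches(
                scaffold, block, i, positions, ligand, cfg, frame, diagnostics)
        else:
            batches = _secondary_batches(
                scaffold, block, i, prior, positions, ligand, cfg)
        diagnostics[f"hits_{i}"] = sum(len(b) for b in batches)
        all_batches.extend(batches)
        prior.extend(batches)

    table = _hash_batches(all_batches, cfg)
    matches = _find_matches_batches(table, len(theozyme.blocks), cfg,
                                    scaffold_id, theozyme, ligand)
    diagnostics["bins"] = len(table)
    diagnostics["matches"] = len(matches)

    if out_dir is not None:
        from pathlib import Path

        from .structure import write_pdb
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = ["match\tscaffold\tbin\tpositions\ttypes\tscore"]
        for j, m in enumerate(matches, start=1):
            st = match_structure(m, scaffold, ligand)
            write_pdb(st, out_dir / f"match_{j:04d}.pdb")
            lines.append("\t".join([
                f"match_{j:04d}", m.scaffold_id, str(m.bin),
                ",".join(f"{c}{n}" for c, n in m.positions),
                ",".join(m.residue_types), f"{m.match_score:.3f}"]))
        (out_dir / "matches.tsv").write_text("\n".join(lines) + "\n")
    return matches, diagnostics
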