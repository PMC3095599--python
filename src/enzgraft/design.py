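"""Active-site design around a grafted theozyme.

The design stage takes a matched model (scaffold + catalytic side chains +
ligand) and optimises the identities and conformations of the surrounding
shell under the catalytic restraints:

1. shell detection — residues are split into designable / repackable /
   static by increasing Calpha distance cuts from the ligand (cut1..cut4,
   with a Cbeta-direction refinement between cuts); catalytic residues are
   always repackable unless explicitly fixed;
2. restraint optimisation (cst_opt) — gradient-based minimisation of the
   ligand rigid body (optionally catalytic chis and shell backbone) with the
   shell mutated to alanine, under a reduced energy without attractive
   terms, Calpha positions restrained to 0.5 A;
3. optional rigid-body Monte-Carlo pre-docking of the ligand (cst_predock);
4. cycles of sequence design (simulated-annealing packing with the ligand
   interaction upweighted and a native-identity bonus) and minimisation,
   restraints on throughout;
5. an unconstrained repack/minimisation of the final sequence, and
   optionally an apo repack with the ligand removed to measure how well the
   designed site holds the catalytic geometry on its own (preorganisation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from . import geometry
from .chem import DESIGNABLE_AA3, RESIDUE_TOPOLOGIES
from .cst import Theozyme, resolve_atom_triples
from .energy import EnergyModel, covalent_exclusions
from .matcher import _chi_samples
from .structure import (BACKBONE_ATOMS, LigandTopology, Residue, Structure,
                        build_side_chain, build_side_chain_batch,
                        measure_chis, residue_from_coords, side_chain_rmsd)

log = logging.getLogger(__name__)

SHELL_LABELS = ("designable", "repackable", "static", "catalytic")


@dataclass
class DesignConfig:
    """Stage-3 protocol settings (flags mirror the command-line options)."""

    cut1: float = 6.0
    cut2: float = 8.0
    cut3: float = 10.0
    cut4: float = 12.0
    design_min_cycles: int = 2
    lig_packer_weight: float = 1.6
    native_bonus: float = 0.8
    trans_magnitude: float = 0.5
    rot_magnitude: float = 5.0
    dock_trials: int = 100
    seed: int = 0
    cst_opt: bool = True
    cst_predock: bool = False
    cst_design: bool = True
    cst_min: bool = True
    bb_min: bool = False
    chi_min: bool = True
    no_unconstrained_repack: bool = False
    fix_catalytic_aa: bool = False
    soft_rep_design: bool = False
    final_repack_without_ligand: bool = False
    ex1: bool = False
    ex2: bool = False
    use_input_sc: bool = True
    max_rotamers_per_pos: int = 25   # one-body pruning cap in the packer

    def __post_init__(self):
        if not (self.cut1 < self.cut2 < self.cut3 < self.cut4):
            raise ValueError("cuts must satisfy cut1 < cut2 < cut3 < cut4")


@dataclass
class ShellAssignment:
    """Exhaustive, exclusive per-residue labels."""

    labels: dict                    # (chain, number) -> label

    def of(self, key) -> str:
        return self.labels[key]

    def keys_with(self, *wanted) -> list:
        return [k for k, v in self.labels.items() if v in wanted]


@dataclass
class PackerTask:
    """Per-position packing behaviour: mode plus allowed residue types."""

    entries: dict                   # key -> (mode, tuple of allowed name3)

    def movable(self) -> list:
        return [k for k, (mode, _) in self.entries.items()
                if mode in ("designable", "repackable", "catalytic")]


# ---------------------------------------------------------------------------
# shell detection
# ---------------------------------------------------------------------------

def detect_design_shell(structure: Structure, cfg: DesignConfig,
                        theozyme: Theozyme | None = None) -> ShellAssignment:
    """Label residues by distance from the ligand (rules applied in order).

    i.  Calpha within cut1 of any ligand heavy atom        -> designable
    ii. Calpha within cut2 and Cbeta closer to that atom   -> designable
    iii. Calpha within cut3                                -> repackable
    iv. Calpha within cut4 and Cbeta closer to that atom   -> repackable
    else static.  Catalytic residues are always repackable (labelled
    ``catalytic``) unless ``fix_catalytic_aa``, which makes them static.
    Glycine, lacking Cbeta, falls back to the Calpha-only test in ii/iv.
    """
    if not structure.ligands:
        raise ValueError("shell detection requires a ligand in the structure")
    lig_xyz = np.concatenate([l.heavy_coords() for l in structure.ligands])
    catalytic = structure.catalytic_keys()
    labels: dict = {}
    for res in structure.residues:
        ca = res.coord("CA")
        da = np.linalg.norm(lig_xyz - ca, axis=1)
        if res.has("CB"):
            db = np.linalg.norm(lig_xyz - res.coord("CB"), axis=1)
        else:
            db = da - 1.0  # no Cbeta: Calpha-only fallback always "closer"
        if np.min(da) < cfg.cut1:
            label = "designable"
        elif np.any((da < cfg.cut2) & (db < da)):
            label = "designable"
        elif np.min(da) < cfg.cut3:
            label = "repackable"
        elif np.any((da < cfg.cut4) & (db < da)):
            label = "repackable"
        else:
            label = "static"
        if res.key in catalytic:
            label = "static" if cfg.fix_catalytic_aa else "catalytic"
        labels[res.key] = label
    return ShellAssignment(labels=labels)


def task_from_shell(structure: Structure, shell: ShellAssignment) -> PackerTask:
    entries = {}
    for res in structure.residues:
        label = shell.of(res.key)
        if label == "designable":
            entries[res.key] = ("designable", tuple(DESIGNABLE_AA3))
        elif label in ("repackable", "catalytic"):
            entries[res.key] = (label, (res.name3,))
        else:
            entries[res.key] = ("static", ())
    return PackerTask(entries=entries)


# ---------------------------------------------------------------------------
# resfile
# ---------------------------------------------------------------------------

_RESFILE_COMMANDS = ("AUTO", "NATRO", "NATAA", "PIKAA", "ALLAA")


def parse_resfile(text) -> tuple:
    """(default command, per-residue commands {(chain, number): (cmd, arg)})."""
    if hasattr(text, "read"):
        text = text.read()
    default = "AUTO"
    per_res: dict = {}
    in_body = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if not in_body:
            if tok[0].lower() == "start":
                in_body = True
            elif tok[0].upper() in _RESFILE_COMMANDS:
                default = tok[0].upper()
            else:
                raise ValueError(f"resfile line {lineno}: unknown header {line!r}")
            continue
        if len(tok) < 3:
            raise ValueError(f"resfile line {lineno}: need 'num chain CMD'")
        number, chain, cmd = int(tok[0]), tok[1], tok[2].upper()
        if cmd not in _RESFILE_COMMANDS[1:]:
            raise ValueError(f"resfile line {lineno}: unknown command {cmd!r}")
        arg = tok[3] if len(tok) > 3 else ""
        if cmd == "PIKAA" and not arg:
            raise ValueError(f"resfile line {lineno}: PIKAA needs residue letters")
        per_res[(chain, number)] = (cmd, arg)
    return default, per_res


def merge_resfile(resfile, shell: ShellAssignment,
                  structure: Structure) -> PackerTask:
    """Resfile commands override; AUTO-covered residues take the shell label."""
    from .chem import expand_residue1

    task = task_from_shell(structure, shell)
    if resfile is None:
        return task
    default, per_res = parse_resfile(resfile)
    for key in per_res:
        structure.find(*key)  # raises for absent residues
    for res in structure.residues:
        key = res.key
        cmd, arg = per_res.get(key, (default, ""))
        if cmd == "AUTO":
            continue  # keep shell-derived entry
        if cmd == "NATRO":
            task.entries[key] = ("static", ())
        elif cmd == "NATAA":
            task.entries[key] = ("repackable", (res.name3,))
        elif cmd == "ALLAA":
            task.entries[key] = ("designable", tuple(DESIGNABLE_AA3))
        elif cmd == "PIKAA":
            task.entries[key] = ("designable", tuple(expand_residue1(arg)))
    return task


# ---------------------------------------------------------------------------
# restraint scoring
# ---------------------------------------------------------------------------

def restraint_scores(structure: Structure, theozyme: Theozyme,
                     ligand_topology: LigandTopology) -> tuple:
    """(total, per-block scores list) for the current coordinates."""
    cat = {i: res for i, res in structure.catalytic_residues()}
    per_block = []
    for bi, block in enumerate(theozyme.blocks, start=1):
        if bi not in cat:
            raise ValueError(f"no catalytic annotation for interaction {bi}")
        res = cat[bi]
        topo = RESIDUE_TOPOLOGIES[res.name3]
        lig_mediated = any(m.is_ligand for m in (block.map1, block.map2))
        if lig_mediated:
            lig = structure.ligand
            t_lig = resolve_atom_triples(block.ligand_map, ligand_topology)
            t_prot = resolve_atom_triples(block.protein_map, topo)
            if block.map1.is_ligand:
                score, _ = geometry.block_score(
                    block, lig.coords_dict(), res.coords_dict(), t_lig, t_prot)
            else:
                score, _ = geometry.block_score(
                    block, res.coords_dict(), lig.coords_dict(), t_prot, t_lig)
        else:
            # residue-residue block: partner 1 is the other catalytic residue
            others = [r for j, r in cat.items() if j != bi]
            score = np.inf
            for other in others:
                s, _ = geometry.block_score(
                    block, other.coords_dict(), res.coords_dict(),
                    resolve_atom_triples(block.map1,
                                         RESIDUE_TOPOLOGIES[other.name3]),
                    resolve_atom_triples(block.map2, topo))
                score = min(score, s)
        per_block.append(float(score))
    return float(sum(per_block)), per_block


# ---------------------------------------------------------------------------
# movable-DOF minimisation
# ---------------------------------------------------------------------------

CA_RESTRAINT_TOL = 0.5    # A
CA_RESTRAINT_K = 50.0


def _restrained_ligand_atoms(theozyme: Theozyme,
                             ligand_topology: LigandTopology) -> list:
    """Ligand atoms carrying a distance restraint to the protein."""
    names = []
    for block in theozyme.blocks:
        if "distanceAB" not in block.params:
            continue
        try:
            lmap = block.ligand_map
        except ValueError:
            continue
        for triple in resolve_atom_triples(lmap, ligand_topology):
            if triple[0] not in names:
                names.append(triple[0])
    return names or ligand_topology.atom_names()


def _unit_arrays(res) -> dict:
    atoms = list(res.atoms.values())
    return {
        "key": res.key,
        "names": list(res.atoms),
        "xyz": np.stack([a.xyz for a in atoms]),
        "rad": np.array([a.radius for a in atoms]),
        "pol": np.array([[a.donor, a.acceptor] for a in atoms], bool),
        "res": res,
    }


def _pair_mask(unit_a: dict, unit_b: dict, exclusions: set) -> np.ndarray | None:
    res_a, res_b = unit_a["res"], unit_b["res"]
    mask = None
    if (res_a.chain == res_b.chain
            and abs(res_a.number - res_b.number) == 1):
        bb_a = np.array([res_a.atoms[n].backbone for n in unit_a["names"]])
        bb_b = np.array([res_b.atoms[n].backbone for n in unit_b["names"]])
        mask = bb_a[:, None] & bb_b[None, :]
    if exclusions:
        for i, na in enumerate(unit_a["names"]):
            ka = (res_a.chain, res_a.number, na)
            for j, nb in enumerate(unit_b["names"]):
                if frozenset((ka, (res_b.chain, res_b.number, nb))) \
                        in exclusions:
                    if mask is None:
                        mask = np.zeros(
                            (len(unit_a["names"]), len(unit_b["names"])), bool)
                    mask[i, j] = True
    return mask


class _DofModel:
    """Applies a DOF vector to a working structure and scores it.

    DOFs: ligand rigid body (tx ty tz rx ry rz, A/deg), then catalytic chi
    angles (if chi_min), then Cartesian shifts of movable backbone atoms
    (if bb_min; side chains ride along with their Calpha shift).  Only
    energy pairs involving moving parts are evaluated — everything else is
    constant and omitted from the objective — and the evaluation runs on
    precomputed atom arrays, not structure copies.
    """

    def __init__(self, structure: Structure, theozyme: Theozyme,
                 ligand_topology: LigandTopology, cfg: DesignConfig,
                 model: EnergyModel, movable_keys: set,
                 move_ligand: bool = True):
        self.base = structure.copy()
        self.theozyme = theozyme
        self.ligand_topology = ligand_topology
        self.cfg = cfg
        self.model = model
        self.move_ligand = move_ligand
        self.reduced = EnergyModel(w_rep=model.w_rep, w_atr=0.0, w_hb=0.0,
                                   w_cst=model.w_cst, soft=model.soft,
                                   reference=model.reference)
        self.exclusions = covalent_exclusions(self.base, theozyme,
                                              ligand_topology)
        lig = self.base.ligand
        self.lig_unit = _unit_arrays(lig)
        self.lig0 = self.lig_unit["xyz"].copy()
        restrained = _restrained_ligand_atoms(theozyme, ligand_topology)
        idx = [self.lig_unit["names"].index(n) for n in restrained]
        self.center = self.lig0[idx].mean(axis=0)

        self.cat_blocks = {res.key: bi
                           for bi, res in self.base.catalytic_residues()}
        self.cat_keys = list(self.cat_blocks)
        self.chi_slices: list = []
        n_dof = 6 if move_ligand else 0
        self.lig_slice = slice(0, 6) if move_ligand else None
        if cfg.chi_min:
            for key in self.cat_keys:
                res = self.base.find(*key)
                n_chi = res.topology.n_chi
                if n_chi:
                    self.chi_slices.append(
                        (key, slice(n_dof, n_dof + n_chi), measure_chis(res)))
                    n_dof += n_chi
        self.bb_keys: list = []
        if cfg.bb_min:
            self.bb_keys = sorted(movable_keys)
            self.bb_slice = slice(n_dof, n_dof + 3 * len(self.bb_keys) * 4)
            n_dof += 3 * len(self.bb_keys) * 4
        self.n_dof = n_dof
        self.ca0 = {key: self.base.find(*key).coord("CA").copy()
                    for key in self.bb_keys}

        self.moving_keys = ({k for k, _, _ in self.chi_slices}
                            | set(self.bb_keys))
        if move_ligand:
            self.moving_keys.add(lig.key)
        self.units = {r.key: _unit_arrays(r) for r in self.base.residues}
        self.units[lig.key] = self.lig_unit
        # precompute, per moving unit, one concatenated static background
        # (plus masks) and the list of moving-moving pairs
        cents = {k: u["xyz"].mean(axis=0) for k, u in self.units.items()}
        self.backgrounds: dict = {}
        moving = sorted(self.moving_keys)
        for m in moving:
            parts, masks = [], []
            um = self.units[m]
            for k, u in self.units.items():
                if k in self.moving_keys:
                    continue
                if np.linalg.norm(cents[m] - cents[k]) > 14.0:
                    continue
                parts.append(u)
                masks.append(_pair_mask(um, u, self.exclusions))
            if parts:
                n_m = len(um["names"])
                mask = None
                if any(mk is not None for mk in masks):
                    mask = np.concatenate(
                        [mk if mk is not None
                         else np.zeros((n_m, len(p["names"])), bool)
                         for mk, p in zip(masks, parts)], axis=1)
                self.backgrounds[m] = (
                    np.concatenate([p["xyz"] for p in parts]),
                    np.concatenate([p["rad"] for p in parts]),
                    np.concatenate([p["pol"] for p in parts]), mask)
        self.moving_pairs = []
        for i, ma in enumerate(moving):
            for mb in moving[i + 1:]:
                if np.linalg.norm(cents[ma] - cents[mb]) > 14.0:
                    continue
                self.moving_pairs.append(
                    (ma, mb, _pair_mask(self.units[ma], self.units[mb],
                                        self.exclusions)))

    def x0(self) -> np.ndarray:
        x = np.zeros(self.n_dof)
        for _, sl, chis in self.chi_slices:
            x[sl] = chis
        return x

    def _moved_arrays(self, x: np.ndarray) -> dict:
        """key -> xyz array for moving units at DOF vector x."""
        out = {}
        if self.move_ligand:
            R = Rotation.from_euler("xyz", x[3:6], degrees=True).as_matrix()
            out[self.lig_unit["key"]] = ((self.lig0 - self.center) @ R.T
                                         + self.center + x[:3])
        bb_shift = {}
        if self.bb_keys:
            shifts = x[self.bb_slice].reshape(len(self.bb_keys), 4, 3)
            for key, sh in zip(self.bb_keys, shifts):
                bb_shift[key] = sh
        for key, sl, _ in self.chi_slices:
            unit = self.units[key]
            res = unit["res"]
            coords = build_side_chain_batch(
                res, res.name3, np.asarray(x[sl]).reshape(1, -1))
            xyz = np.stack([
                np.asarray(coords[n][0] if coords[n].ndim == 2 else coords[n])
                for n in unit["names"]])
            out[key] = xyz
        for key in self.bb_keys:
            unit = self.units[key]
            xyz = out.get(key, unit["xyz"]).copy()
            sh = bb_shift[key]
            ca_shift = sh[BACKBONE_ATOMS.index("CA")]
            for i, n in enumerate(unit["names"]):
                if n in BACKBONE_ATOMS:
                    xyz[i] = xyz[i] + sh[BACKBONE_ATOMS.index(n)]
                else:
                    xyz[i] = xyz[i] + ca_shift  # side chain rides the Calpha
            out[key] = xyz
        return out

    def _coords_dict(self, key, moved: dict) -> dict:
        unit = self.units[key]
        xyz = moved.get(key, unit["xyz"])
        return dict(zip(unit["names"], xyz))

    def restraints(self, moved: dict) -> float:
        total = 0.0
        lig_key = self.lig_unit["key"]
        for key, bi in self.cat_blocks.items():
            block = self.theozyme.blocks[bi - 1]
            res = self.units[key]["res"]
            topo = RESIDUE_TOPOLOGIES[res.name3]
            lig_mediated = any(m.is_ligand for m in (block.map1, block.map2))
            res_coords = self._coords_dict(key, moved)
            if lig_mediated:
                lig_coords = self._coords_dict(lig_key, moved)
                t_lig = resolve_atom_triples(block.ligand_map,
                                             self.ligand_topology)
                t_prot = resolve_atom_triples(block.protein_map, topo)
                if block.map1.is_ligand:
                    s, _ = geometry.block_score(block, lig_coords, res_coords,
                                                t_lig, t_prot)
                else:
                    s, _ = geometry.block_score(block, res_coords, lig_coords,
                                                t_prot, t_lig)
            else:
                s = np.inf
                for other_key, oi in self.cat_blocks.items():
                    if other_key == key:
                        continue
                    other = self.units[other_key]["res"]
                    sc, _ = geometry.block_score(
                        block, self._coords_dict(other_key, moved), res_coords,
                        resolve_atom_triples(block.map1,
                                             RESIDUE_TOPOLOGIES[other.name3]),
                        resolve_atom_triples(block.map2, topo))
                    s = min(s, sc)
            total += float(s)
        return total

    def objective(self, x: np.ndarray, include_atr: bool) -> float:
        moved = self._moved_arrays(x)
        model = self.model if include_atr else self.reduced
        e = model.w_cst * self.restraints(moved)
        for m, (bx, br, bp, mask) in self.backgrounds.items():
            um = self.units[m]
            terms = model.pair_terms(
                moved.get(m, um["xyz"]), um["rad"], um["pol"],
                bx, br, bp, mask)
            e += terms["rep"] + terms["atr"] + terms["hb"]
        for ka, kb, mask in self.moving_pairs:
            ua, ub = self.units[ka], self.units[kb]
            terms = model.pair_terms(
                moved.get(ka, ua["xyz"]), ua["rad"], ua["pol"],
                moved.get(kb, ub["xyz"]), ub["rad"], ub["pol"], mask)
            e += terms["rep"] + terms["atr"] + terms["hb"]
        for key in self.bb_keys:
            unit = self.units[key]
            ca_idx = unit["names"].index("CA")
            d = np.linalg.norm(moved.get(key, unit["xyz"])[ca_idx]
                               - self.ca0[key])
            e += CA_RESTRAINT_K * max(0.0, d - CA_RESTRAINT_TOL) ** 2
        return float(e)

    def apply(self, x: np.ndarray) -> Structure:
        st = self.base.copy()
        moved = self._moved_arrays(x)
        for key, xyz in moved.items():
            unit = self.units[key]
            target = (st.ligand if key == self.lig_unit["key"]
                      else st.find(*key))
            for name, v in zip(unit["names"], xyz):
                target.atoms[name].xyz = np.asarray(v, float)
        st.reindex()
        return st


def _minimise(dof: _DofModel, include_atr: bool,
              maxiter: int = 60) -> tuple:
    best = {"x": dof.x0(), "f": dof.objective(dof.x0(), include_atr)}

    def fun(x):
        f = dof.objective(x, include_atr)
        if f < best["f"]:
            best["f"], best["x"] = f, x.copy()
        return f

    res = _scipy_minimize(fun, dof.x0(), method="L-BFGS-B",
                          options={"maxiter": maxiter, "ftol": 1e-9,
                                   "eps": 1e-4})
    if not res.success:
        log.warning("minimisation did not converge: %s; best-so-far returned",
                    res.message)
    return dof.apply(best["x"]), best["f"]


# ---------------------------------------------------------------------------
# cst_opt / cst_predock
# ---------------------------------------------------------------------------

def cst_opt(structure: Structure, theozyme: Theozyme,
            ligand_topology: LigandTopology, cfg: DesignConfig,
            model: EnergyModel | None = None,
            shell: ShellAssignment | None = None) -> Structure:
    """Optimise the catalytic geometry before design.

    Designable/repackable non-catalytic residues are mutated to alanine and
    the ligand rigid body (plus catalytic chis with chi_min, shell backbone
    with bb_min) is minimised under a reduced energy without attractive
    terms, with restraints on and Calpha positions restrained to 0.5 A.
    Static-region coordinates are untouched.
    """
    model = model or EnergyModel()
    shell = shell or detect_design_shell(structure, cfg)
    st = structure.copy()
    for key in shell.keys_with("designable", "repackable"):
        res = st.find(*key)
        if res.name3 not in ("ALA", "GLY"):
            mutated = build_side_chain(res, "ALA", [])
            res.name3, res.atoms = "ALA", mutated.atoms
    st.reindex()
    movable = set(shell.keys_with("designable", "repackable", "catalytic"))
    dof = _DofModel(st, theozyme, ligand_topology, cfg, model, movable)
    out, _ = _minimise(dof, include_atr=False)
    return out


def cst_predock(structure: Structure, theozyme: Theozyme,
                ligand_topology: LigandTopology, cfg: DesignConfig,
                model: EnergyModel | None = None,
                shell: ShellAssignment | None = None) -> Structure:
    """Monte-Carlo rigid-body pre-docking of the ligand under restraints.

    Translations are Gaussian with scale ``trans_magnitude`` per axis;
    rotations Gaussian with scale ``rot_magnitude`` about a random axis
    through the centroid of the distance-restrained ligand atoms.
    Designable residues are mutated to alanine first.  The lowest-energy
    visited pose is returned; ``dock_trials == 0`` leaves the structure
    untouched.
    """
    model = model or EnergyModel()
    st = structure.copy()
    if cfg.dock_trials == 0:
        return st
    shell = shell or detect_design_shell(structure, cfg)
    for key in shell.keys_with("designable"):
        res = st.find(*key)
        if res.name3 not in ("ALA", "GLY"):
            mutated = build_side_chain(res, "ALA", [])
            res.name3, res.atoms = "ALA", mutated.atoms
    st.reindex()
    rng = np.random.default_rng(cfg.seed)
    exclusions = covalent_exclusions(st, theozyme, ligand_topology)
    restrained = _restrained_ligand_atoms(theozyme, ligand_topology)

    def energy(struct) -> float:
        cst, _ = restraint_scores(struct, theozyme, ligand_topology)
        lig = struct.ligand
        e = model.w_cst * cst
        for res in struct.residues:
            if np.linalg.norm(res.coord("CA")
                              - lig.heavy_coords().mean(axis=0)) > 14.0:
                continue
            terms = model.residue_pair_energy(res, lig, exclusions)
            e += terms["rep"] + terms["atr"] + terms["hb"]
        return float(e)

    current = st
    e_cur = energy(current)
    best, e_best = current, e_cur
    for _ in range(cfg.dock_trials):
        trial = current.copy()
        lig = trial.ligand
        center = np.mean([lig.coord(n) for n in restrained], axis=0)
        t = rng.normal(size=3) * cfg.trans_magnitude
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.normal() * cfg.rot_magnitude
        R = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
        for a in lig.atoms.values():
            a.xyz = R @ (a.xyz - center) + center + t
        e_new = energy(trial)
        if e_new <= e_cur or rng.random() < np.exp(-(e_new - e_cur)):
            current, e_cur = trial, e_new
            if e_cur < e_best:
                best, e_best = current, e_cur
    return best


# ---------------------------------------------------------------------------
# packer
# ---------------------------------------------------------------------------

def _rotamer_arrays(res: Residue, name3: str, chis) -> tuple:
    """(names, xyz, radii, polarity) of CB + side-chain atoms for one rotamer."""
    topo = RESIDUE_TOPOLOGIES[name3]
    coords = build_side_chain_batch(res, name3, np.atleast_2d(
        np.asarray(chis, float).reshape(1, -1)))
    names, xyz, rad, pol = [], [], [], []
    from .chem import VDW_RADII
    if topo.has_cb:
        names.append("CB")
        xyz.append(coords["CB"])
        rad.append(VDW_RADII["C"])
        pol.append((False, False))
    for sc in topo.side_chain:
        v = coords[sc.name]
        names.append(sc.name)
        xyz.append(v[0] if v.ndim == 2 else v)
        rad.append(VDW_RADII.get(sc.element.upper(), 1.7))
        pol.append((sc.donor, sc.acceptor))
    if not names:
        return [], np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2), bool)
    return names, np.stack(xyz), np.asarray(rad), np.asarray(pol, bool)


@dataclass
class _PackRotamer:
    name3: str
    chi: tuple
    names: list
    xyz: np.ndarray
    rad: np.ndarray
    pol: np.ndarray
    one_body: float = 0.0
    one_body_lig: float = 0.0      # unscaled ligand contribution


def _position_rotamers(res: Residue, allowed, cfg: DesignConfig) -> list:
    out = []
    for name3 in allowed:
        topo = RESIDUE_TOPOLOGIES[name3]
        combos = _chi_samples(topo.n_chi, cfg.ex1, cfg.ex2)
        if cfg.use_input_sc and res.name3 == name3 and topo.n_chi > 0:
            try:
                combos = combos + [tuple(measure_chis(res))]
            except Exception:
                pass
        for chis in combos:
            names, xyz, rad, pol = _rotamer_arrays(res, name3, list(chis))
            out.append(_PackRotamer(name3, tuple(chis), names, xyz, rad, pol))
    return out


_PAD_XYZ = 1e6  # padding atoms sit far away; every pair term vanishes there


def _pad_rotamers(rots: list) -> dict:
    """Stack a position's rotamer atoms into padded (R, A, ...) arrays."""
    n_max = max((len(r.names) for r in rots), default=0)
    R = len(rots)
    xyz = np.full((R, max(n_max, 1), 3), _PAD_XYZ)
    rad = np.zeros((R, max(n_max, 1)))
    pol = np.zeros((R, max(n_max, 1), 2), bool)
    for i, r in enumerate(rots):
        if len(r.names):
            xyz[i, :len(r.names)] = r.xyz
            rad[i, :len(r.names)] = r.rad
            pol[i, :len(r.names)] = r.pol
    return {"xyz": xyz, "rad": rad, "pol": pol}


def _pair_table(pa: dict, pb: dict, model: EnergyModel) -> np.ndarray:
    """(R_a, R_b) table of summed pair energies between two rotamer sets."""
    diff = (pa["xyz"][:, None, :, None, :] - pb["xyz"][None, :, None, :, :])
    d = np.sqrt(np.einsum("abijk,abijk->abij", diff, diff))
    d = np.maximum(d, 1e-6)
    sigma = pa["rad"][:, None, :, None] + pb["rad"][None, :, None, :]
    real = sigma > 0  # padding atoms carry zero radius

    from .energy import (ATR_CUTOFF, HB_CUTOFF, HB_IDEAL, HB_WIDTH,
                         REP_FACTOR_HARD, REP_FACTOR_SOFT)
    rep_sigma = sigma * (REP_FACTOR_SOFT if model.soft else REP_FACTOR_HARD)
    rep = np.zeros_like(d)
    inside = (d < rep_sigma) & real
    rep[inside] = np.minimum(model.rep_cap,
                             (rep_sigma[inside] / d[inside]) ** 12 - 1.0)
    shift = np.zeros_like(d)
    shift[real] = (sigma[real] / ATR_CUTOFF) ** 6
    atr = np.zeros_like(d)
    in_well = (d >= sigma) & (d <= ATR_CUTOFF) & real
    atr[in_well] = (sigma[in_well] / d[in_well]) ** 6 - shift[in_well]
    clamped = (d < sigma) & real
    atr[clamped] = 1.0 - shift[clamped]
    hb_pair = ((pa["pol"][:, None, :, None, 0] & pb["pol"][None, :, None, :, 1])
               | (pa["pol"][:, None, :, None, 1] & pb["pol"][None, :, None, :, 0]))
    hb = np.zeros_like(d)
    sel = hb_pair & (d <= HB_CUTOFF)
    hb[sel] = np.exp(-((d[sel] - HB_IDEAL) ** 2) / (2.0 * HB_WIDTH ** 2))
    total = (model.w_rep * rep - model.w_atr * atr - model.w_hb * hb)
    return np.sum(total, axis=(2, 3))


def one_body_energies(st: Structure, key, task: PackerTask, cfg: DesignConfig,
                      model: EnergyModel, background, lig_arrays,
                      lig_weight: float, cat_blocks: dict,
                      ligand_topology) -> list:
    """Rotamers at one position with their one-body energies filled in.

    ``one_body`` sums the interaction with the fixed background, the ligand
    interaction scaled by ``lig_weight``, the residue-type reference energy,
    minus the native bonus for the native identity at designable positions,
    plus (for catalytic positions with restraints on) the restraint score of
    the rotamer against the ligand.  The unscaled ligand contribution is
    kept in ``one_body_lig`` so callers can inspect the upweighting.
    """
    bg_xyz, bg_rad, bg_pol = background
    res = st.find(*key)
    mode, allowed = task.entries[key]
    rots = _position_rotamers(res, allowed, cfg)
    native_type = res.name3
    lig = st.ligand if st.ligands else None
    for r in rots:
        e = model.reference.get(r.name3, 0.0)
        if mode == "designable" and r.name3 == native_type:
            e -= cfg.native_bonus
        e_lig = 0.0
        if len(r.names):
            terms = model.pair_terms(r.xyz, r.rad, r.pol,
                                     bg_xyz, bg_rad, bg_pol)
            e += terms["rep"] + terms["atr"] + terms["hb"]
            if lig_arrays is not None:
                lx, lr, lp = lig_arrays
                lt = model.pair_terms(r.xyz, r.rad, r.pol, lx, lr, lp)
                e_lig = lt["rep"] + lt["atr"] + lt["hb"]
                e += lig_weight * e_lig
        if key in cat_blocks and ligand_topology is not None and lig is not None:
            trial = residue_from_coords(
                res, r.name3,
                {**{n: res.coord(n) for n in BACKBONE_ATOMS},
                 **dict(zip(r.names, r.xyz))})
            for block in cat_blocks[key]:
                try:
                    t_prot = resolve_atom_triples(
                        block.protein_map, RESIDUE_TOPOLOGIES[r.name3])
                    t_lig = resolve_atom_triples(block.ligand_map,
                                                 ligand_topology)
                except (KeyError, ValueError):
                    e += 1e3
                    continue
                if block.map1.is_ligand:
                    s, _ = geometry.block_score(
                        block, lig.coords_dict(), trial.coords_dict(),
                        t_lig, t_prot)
                else:
                    s, _ = geometry.block_score(
                        block, trial.coords_dict(), lig.coords_dict(),
                        t_prot, t_lig)
                e += model.w_cst * (s if np.isfinite(s) else 1e3)
        r.one_body = e
        r.one_body_lig = e_lig
    return rots


def packer_background(structure: Structure, task: PackerTask) -> tuple:
    """(background arrays, ligand arrays or None) as the packer sees them."""
    movable_set = {k for k in task.movable() if task.entries[k][1]}
    bg_xyz, bg_rad, bg_pol = [], [], []
    for res in structure.residues:
        names = (res.atoms if res.key not in movable_set
                 else [n for n in BACKBONE_ATOMS if n in res.atoms])
        for n in names:
            a = res.atoms[n]
            bg_xyz.append(a.xyz)
            bg_rad.append(a.radius)
            bg_pol.append((a.donor, a.acceptor))
    lig_arrays = (EnergyModel._arrays(structure.ligand)
                  if structure.ligands else None)
    return ((np.stack(bg_xyz), np.asarray(bg_rad), np.asarray(bg_pol, bool)),
            lig_arrays)


def pack_structure(structure: Structure, task: PackerTask, cfg: DesignConfig,
                   model: EnergyModel,
                   theozyme: Theozyme | None = None,
                   ligand_topology: LigandTopology | None = None,
                   lig_weight: float | None = None,
                   with_restraints: bool = True,
                   rng: np.random.Generator | None = None) -> Structure:
    """Simulated-annealing rotamer/identity packing.

    One-body energies cover the fixed background (static residues, movable
    backbones, the ligand scaled by ``lig_weight``), reference energies, the
    native-identity bonus at designable positions, and — when restraints are
    on — the restraint score of catalytic rotamers against the ligand.
    Two-body energies couple side chains of movable position pairs.  The
    annealer cools geometrically and returns the best assignment visited.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lig_weight = cfg.lig_packer_weight if lig_weight is None else lig_weight
    model = EnergyModel(w_rep=model.w_rep, w_atr=model.w_atr, w_hb=model.w_hb,
                        w_cst=model.w_cst, soft=cfg.soft_rep_design,
                        reference=model.reference)
    st = structure.copy()
    movable = [k for k in task.movable() if task.entries[k][1]]
    if not movable:
        return st
    cat_blocks: dict = {}
    if theozyme is not None:
        for bi, res in st.catalytic_residues():
            cat_blocks.setdefault(res.key, []).append(
                theozyme.blocks[bi - 1])

    # fixed background: static residues (all atoms) + movable backbones
    bg_xyz, bg_rad, bg_pol = [], [], []
    movable_set = set(movable)
    for res in st.residues:
        names = (res.atoms if res.key not in movable_set
                 else [n for n in BACKBONE_ATOMS if n in res.atoms])
        for n in names:
            a = res.atoms[n]
            bg_xyz.append(a.xyz)
            bg_rad.append(a.radius)
            bg_pol.append((a.donor, a.acceptor))
    bg_xyz = np.stack(bg_xyz)
    bg_rad = np.asarray(bg_rad)
    bg_pol = np.asarray(bg_pol, bool)
    has_lig = bool(st.ligands)
    if has_lig:
        lig = st.ligand
        lx, lr, lp = EnergyModel._arrays(lig)

    # rotamer sets with one-body energies, pruned
    rotamers: dict = {}
    for key in movable:
        rots = one_body_energies(
            st, key, task, cfg, model,
            (bg_xyz, bg_rad, bg_pol),
            (lx, lr, lp) if has_lig else None,
            lig_weight, cat_blocks if with_restraints else {},
            ligand_topology)
        rots.sort(key=lambda r: r.one_body)
        rotamers[key] = rots[: cfg.max_rotamers_per_pos]

    # two-body tables for close position pairs, padded-array vectorised
    positions = list(rotamers)
    ca = {k: st.find(*k).coord("CA") for k in positions}
    padded = {p: _pad_rotamers(rotamers[p]) for p in positions}
    pair_tables: dict = {}
    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            if np.linalg.norm(ca[p] - ca[q]) > 14.0:
                continue
            pair_tables[(p, q)] = _pair_table(padded[p], padded[q], model)

    def pair_e(p, q, a, b) -> float:
        if (p, q) in pair_tables:
            return pair_tables[(p, q)][a, b]
        if (q, p) in pair_tables:
            return pair_tables[(q, p)][b, a]
        return 0.0

    # annealing
    state = {p: int(rng.integers(len(rotamers[p]))) for p in positions}

    def total(state) -> float:
        e = sum(rotamers[p][state[p]].one_body for p in positions)
        for i, p in enumerate(positions):
            for q in positions[i + 1:]:
                e += pair_e(p, q, state[p], state[q])
        return e

    e_cur = total(state)
    best_state, e_best = dict(state), e_cur
    temps = 10.0 * (0.05 / 10.0) ** (np.arange(12) / 11.0)
    for kT in temps:
        for _ in range(20 * len(positions)):
            p = positions[int(rng.integers(len(positions)))]
            new = int(rng.integers(len(rotamers[p])))
            if new == state[p]:
                continue
            delta = (rotamers[p][new].one_body
                     - rotamers[p][state[p]].one_body)
            for q in positions:
                if q == p:
                    continue
                delta += (pair_e(p, q, new, state[q])
                          - pair_e(p, q, state[p], state[q]))
            if delta <= 0 or rng.random() < np.exp(-delta / kT):
                state[p] = new
                e_cur += delta
                if e_cur < e_best:
                    best_state, e_best = dict(state), e_cur

    for p in positions:
        r = rotamers[p][best_state[p]]
        res = st.find(*p)
        rebuilt = build_side_chain(res, r.name3, list(r.chi))
        res.name3, res.atoms = r.name3, rebuilt.atoms
        for ann in st.annotations:
            if (ann.chain, ann.number) == p:
                ann.name3 = r.name3
    st.reindex()
    return st


# ---------------------------------------------------------------------------
# design cycles and final repacks
# ---------------------------------------------------------------------------

def design_cycle(structure: Structure, task: PackerTask, theozyme: Theozyme,
                 ligand_topology: LigandTopology, cfg: DesignConfig,
                 model: EnergyModel | None = None) -> Structure:
    """``design_min_cycles`` iterations of [sequence packing + minimisation].

    Protein-ligand interactions are upweighted by ``lig_packer_weight`` in
    the packer, the native identity at designable positions receives
    ``native_bonus``, and the catalytic restraints stay on throughout.
    """
    model = model or EnergyModel()
    st = structure.copy()
    rng = np.random.default_rng(cfg.seed)
    for cycle in range(cfg.design_min_cycles):
        st = pack_structure(st, task, cfg, model, theozyme, ligand_topology,
                            rng=rng)
        if cfg.cst_min:
            movable = set(task.movable())
            dof = _DofModel(st, theozyme, ligand_topology, cfg, model, movable)
            st, _ = _minimise(dof, include_atr=True)
    return st


def unconstrained_repack(structure: Structure, theozyme: Theozyme,
                         ligand_topology: LigandTopology, cfg: DesignConfig,
                         model: EnergyModel | None = None,
                         task: PackerTask | None = None) -> tuple:
    """Fixed-sequence repack (+ minimisation) with restraints off.

    Returns (structure, stage weights log).  Skipped entirely under
    ``no_unconstrained_repack``.
    """
    model = model or EnergyModel()
    weights = {"cst": 0.0}
    if cfg.no_unconstrained_repack:
        return structure.copy(), weights
    st = structure.copy()
    if task is None:
        shell = detect_design_shell(st, cfg)
        task = task_from_shell(st, shell)
    repack_task = PackerTask(entries={
        k: (("repackable", (st.find(*k).name3,))
            if mode in ("designable", "repackable", "catalytic")
            else (mode, allowed))
        for k, (mode, allowed) in task.entries.items()})
    st = pack_structure(st, repack_task, cfg, model, theozyme,
                        ligand_topology, lig_weight=1.0,
                        with_restraints=False,
                        rng=np.random.default_rng(cfg.seed + 1))
    if cfg.cst_min:
        no_cst = EnergyModel(w_rep=model.w_rep, w_atr=model.w_atr,
                             w_hb=model.w_hb, w_cst=0.0,
                             reference=model.reference)
        movable = set(repack_task.movable())
        # the ligand rigid body stays fixed: without restraints an unbound
        # ligand is the energy optimum, and this stage probes whether the
        # designed protein holds the catalytic conformations, not binding
        dof = _DofModel(st, theozyme, ligand_topology, cfg, no_cst, movable,
                        move_ligand=False)
        st, _ = _minimise(dof, include_atr=True)
    return st, weights


def repack_without_ligand(structure: Structure, theozyme: Theozyme,
                          ligand_topology: LigandTopology, cfg: DesignConfig,
                          model: EnergyModel | None = None) -> tuple:
    """Remove the ligand, repack, and report catalytic side-chain RMSDs.

    Returns (apo structure, {block_index: rmsd}, mean rmsd over catalytic
    residues) — the preorganisation measure: small RMSDs mean the designed
    site holds the catalytic conformations without the ligand.
    """
    model = model or EnergyModel()
    if not structure.ligands:
        raise ValueError("repack_without_ligand needs a liganded structure")
    shell = detect_design_shell(structure, cfg)
    apo = structure.copy()
    apo.ligands = []
    task = task_from_shell(apo, shell)
    repack_task = PackerTask(entries={
        k: (("repackable", (apo.find(*k).name3,))
            if mode in ("designable", "repackable", "catalytic")
            else (mode, allowed))
        for k, (mode, allowed) in task.entries.items()})
    apo = pack_structure(apo, repack_task, cfg, model,
                         with_restraints=False,
                         rng=np.random.default_rng(cfg.seed + 2))
    rmsds = {}
    for bi, res in structure.catalytic_residues():
        rmsds[bi] = side_chain_rmsd(res, apo.find(res.chain, res.number))
    mean = float(np.mean(list(rmsds.values()))) if rmsds else 0.0
    return apo, rmsds, mean


def run_design(structure: Structure, theozyme: Theozyme,
               ligand_topology: LigandTopology, cfg: DesignConfig,
               model: EnergyModel | None = None,
               resfile=None) -> dict:
    """The full design stage on one matched model.

    Returns {'structure', 'shell', 'task', 'apo_rmsds', 'apo_mean_rmsd'}.
    """
    model = model or EnergyModel()
    shell = detect_design_shell(structure, cfg, theozyme)
    task = merge_resfile(resfile, shell, structure)
    st = structure.copy()
    trace = {"input": restraint_scores(st, theozyme, ligand_topology)[0]}
    if cfg.cst_opt:
        st = cst_opt(st, theozyme, ligand_topology, cfg, model, shell)
        trace["cst_opt"] = restraint_scores(st, theozyme, ligand_topology)[0]
    if cfg.cst_predock:
        st = cst_predock(st, theozyme, ligand_topology, cfg, model, shell)
        trace["cst_predock"] = restraint_scores(st, theozyme,
                                                ligand_topology)[0]
    if cfg.cst_design:
        st = design_cycle(st, task, theozyme, ligand_topology, cfg, model)
        trace["design"] = restraint_scores(st, theozyme, ligand_topology)[0]
    st, _ = unconstrained_repack(st, theozyme, ligand_topology, cfg, model,
                                 task)
    trace["unconstrained"] = restraint_scores(st, theozyme,
                                              ligand_topology)[0]
    out = {"structure": st, "shell": shell, "task": task,
           "restraint_trace": trace,
           "apo_rmsds": {}, "apo_mean_rmsd": 0.0}
    if cfg.final_repack_without_ligand:
        _, rmsds, mean = repack_without_ligand(st, theozyme, ligand_topology,
                                               cfg, model)
        out["apo_rmsds"] = rmsds
        out["apo_mean_rmsd"] = mean
    return out
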