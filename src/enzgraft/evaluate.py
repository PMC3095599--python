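"""Per-design metrics, scorefile emission, and cutoff-based ranking.

A finished design is summarised by a metric vector: total energy (restraints
excluded), repulsive and side-chain hydrogen-bond components, the restraint
score in total and per constrained residue (columns SR1..SRN for the N
catalytic residues, SR(N+1) for the ligand — the ligand is always the last
SR), the protein-ligand interface score, packing proxies with and without
the ligand, buried unsatisfied polar atoms, non-local contacts, hydrogen
bond counts, and apo-repack RMSDs of the catalytic residues
(preorganisation).  Records are written one line per design to a
whitespace-delimited scorefile, and designs are selected by a list of
metric/comparator/threshold cutoffs, several of which are naturally
expressed relative to a repacked reference structure.

Geometric criteria (documented defaults, configurable):
hydrogen bond = donor/acceptor heavy atoms of different residues within
3.3 A with base-donor-acceptor angle >= 120 deg; burial = >= 12 heavy-atom
neighbours within 5.2 A (other residues); non-local contact = residue pair
with sequence separation >= 6 and any heavy-atom distance <= 4.5 A.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .chem import RESIDUE_TOPOLOGIES
from .cst import Theozyme
from .design import (DesignConfig, PackerTask, _DofModel, _minimise,
                     detect_design_shell, pack_structure, repack_without_ligand,
                     restraint_scores, task_from_shell)
from .energy import EnergyModel
from .structure import LigandTopology, Structure

HB_MAX_DIST = 3.3
HB_MIN_ANGLE = 120.0
BURIAL_RADIUS = 5.2
BURIAL_NEIGHBORS = 12
NONLOCAL_MIN_SEP = 6
NONLOCAL_MAX_DIST = 4.5
PACKING_N_REF = 12


# ---------------------------------------------------------------------------
# atom enumeration helpers
# ---------------------------------------------------------------------------

def _atom_table(structure: Structure, include_ligand: bool = True,
                ligand_topology: LigandTopology | None = None) -> dict:
    """Flat arrays over all heavy atoms with residue bookkeeping."""
    xyz, res_idx, donor, acceptor, backbone, names = [], [], [], [], [], []
    units = list(structure.residues) + (
        list(structure.ligands) if include_ligand else [])
    for i, res in enumerate(units):
        for name, a in res.atoms.items():
            xyz.append(a.xyz)
            res_idx.append(i)
            donor.append(a.donor)
            acceptor.append(a.acceptor)
            backbone.append(a.backbone)
            names.append(name)
    return {
        "xyz": np.stack(xyz), "res": np.asarray(res_idx),
        "donor": np.asarray(donor, bool), "acceptor": np.asarray(acceptor, bool),
        "backbone": np.asarray(backbone, bool), "names": names,
        "units": units,
    }


def _donor_base(res, atom_name: str,
                ligand_topology: LigandTopology | None) -> str | None:
    if res.is_ligand:
        if ligand_topology is None:
            return None
        try:
            return ligand_topology.parent_of(atom_name)
        except KeyError:
            return None
    if atom_name == "N":
        return "CA"
    topo = RESIDUE_TOPOLOGIES.get(res.name3)
    if topo is None:
        return None
    try:
        return topo.parent_of(atom_name)
    except KeyError:
        return None


def enumerate_hbonds(structure: Structure,
                     ligand_topology: LigandTopology | None = None,
                     max_dist: float = HB_MAX_DIST,
                     min_angle: float = HB_MIN_ANGLE) -> list:
    """Unique hydrogen-bonded atom pairs under the geometric criterion.

    Returns [((unit_i, name), (unit_j, name)), ...] with i, j unit indices
    into residues-then-ligands order; each unordered pair appears once.
    """
    tab = _atom_table(structure, include_ligand=True)
    xyz = tab["xyz"]
    found = set()
    donors = np.nonzero(tab["donor"])[0]
    acceptors = np.nonzero(tab["acceptor"])[0]
    if donors.size == 0 or acceptors.size == 0:
        return []
    d2 = np.sum((xyz[donors][:, None, :] - xyz[acceptors][None, :, :]) ** 2,
                axis=-1)
    close = np.nonzero(d2 <= max_dist ** 2)
    for di, ai in zip(*close):
        d_idx, a_idx = donors[di], acceptors[ai]
        if tab["res"][d_idx] == tab["res"][a_idx]:
            continue
        res_d = tab["units"][tab["res"][d_idx]]
        base = _donor_base(res_d, tab["names"][d_idx], ligand_topology)
        if base is None or base not in res_d.atoms:
            continue
        try:
            ang = float(geometry.angle(res_d.coord(base), xyz[d_idx],
                                       xyz[a_idx]))
        except geometry.DegenerateGeometryError:
            continue
        if ang < min_angle:
            continue
        pair = frozenset(((int(tab["res"][d_idx]), tab["names"][d_idx]),
                          (int(tab["res"][a_idx]), tab["names"][a_idx])))
        found.add(pair)
    out = []
    for pair in found:
        a, b = sorted(pair)
        out.append((a, b))
    return sorted(out)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def count_hbonds(structure: Structure,
                 ligand_topology: LigandTopology | None = None) -> tuple:
    """(total hydrogen bonds, bonds involving a catalytic residue)."""
    bonds = enumerate_hbonds(structure, ligand_topology)
    tab = _atom_table(structure, include_ligand=True)
    cat = structure.catalytic_keys()
    cat_units = {i for i, u in enumerate(tab["units"])
                 if (u.chain, u.number) in cat and not u.is_ligand}
    n_cat = sum(1 for (ia, _), (ib, _) in bonds
                if ia in cat_units or ib in cat_units)
    return len(bonds), n_cat


def _neighbor_counts(structure: Structure, include_ligand: bool) -> tuple:
    tab = _atom_table(structure, include_ligand=include_ligand)
    xyz = tab["xyz"]
    n = xyz.shape[0]
    counts = np.zeros(n, int)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    within = (d2 <= BURIAL_RADIUS ** 2) \
        & (tab["res"][:, None] != tab["res"][None, :])
    counts = within.sum(axis=1)
    return counts, tab


def count_buried_unsat(structure: Structure,
                       ligand_topology: LigandTopology | None = None) -> tuple:
    """(buried unsatisfied polar atoms, catalytic-residue subset).

    A polar (donor or acceptor) atom with at least ``BURIAL_NEIGHBORS``
    heavy-atom neighbours within ``BURIAL_RADIUS`` from other residues and
    no hydrogen bond is counted.
    """
    counts, tab = _neighbor_counts(structure, include_ligand=True)
    bonds = enumerate_hbonds(structure, ligand_topology)
    bonded = set()
    for (ia, na), (ib, nb) in bonds:
        bonded.add((ia, na))
        bonded.add((ib, nb))
    cat = structure.catalytic_keys()
    total = 0
    n_cat = 0
    for idx in np.nonzero(tab["donor"] | tab["acceptor"])[0]:
        if counts[idx] < BURIAL_NEIGHBORS:
            continue
        unit_i = int(tab["res"][idx])
        if (unit_i, tab["names"][idx]) in bonded:
            continue
        total += 1
        unit = tab["units"][unit_i]
        if not unit.is_ligand and (unit.chain, unit.number) in cat:
            n_cat += 1
    return total, n_cat


def count_nonlocal_contacts(structure: Structure,
                            min_separation: int = NONLOCAL_MIN_SEP,
                            max_dist: float = NONLOCAL_MAX_DIST) -> tuple:
    """(non-local residue contact pairs, pairs involving catalytic residues).

    A contact is a residue pair with |i - j| >= min_separation (different
    chains always count as non-local) and any heavy-atom distance within
    ``max_dist``; each unordered pair is counted once.
    """
    residues = structure.residues
    cat = structure.catalytic_keys()
    total = 0
    n_cat = 0
    for i in range(len(residues)):
        xi = residues[i].heavy_coords()
        for j in range(i + 1, len(residues)):
            ra, rb = residues[i], residues[j]
            if ra.chain == rb.chain and abs(ra.number - rb.number) < min_separation:
                continue
            xj = rb.heavy_coords()
            d2 = np.sum((xi[:, None, :] - xj[None, :, :]) ** 2, axis=-1)
            if np.min(d2) <= max_dist ** 2:
                total += 1
                if ra.key in cat or rb.key in cat:
                    n_cat += 1
    return total, n_cat


def packing_metric(structure: Structure, with_ligand: bool = True) -> float:
    """A packing proxy in [0, 1]: mean capped neighbour occupancy.

    Per heavy atom, occupancy = min(1, n / PACKING_N_REF) with n the count
    of other-residue heavy atoms within BURIAL_RADIUS; the metric is the
    mean over all atoms.  Dense cores approach 1, isolated atoms score 0.
    Reported with the ligand present and, separately, with it removed.
    """
    counts, _ = _neighbor_counts(structure, include_ligand=with_ligand)
    if counts.size == 0:
        return 0.0
    occ = np.minimum(1.0, counts / PACKING_N_REF)
    return float(np.mean(occ))


def interface_score(structure: Structure,
                    model: EnergyModel | None = None) -> float:
    """Protein-ligand interaction energy (pair terms only, no restraints)."""
    model = model or EnergyModel()
    if not structure.ligands:
        raise ValueError("interface score requires a ligand")
    total = 0.0
    for lig in structure.ligands:
        lc = lig.heavy_coords().mean(axis=0)
        span = float(np.max(np.linalg.norm(lig.heavy_coords() - lc, axis=1)))
        for res in structure.residues:
            if np.linalg.norm(res.coord("CA") - lc) > span + 12.0:
                continue
            terms = model.residue_pair_energy(res, lig)
            total += terms["rep"] + terms["atr"] + terms["hb"]
    return float(total)


def hbond_sidechain_score(structure: Structure,
                          model: EnergyModel | None = None,
                          ligand_topology: LigandTopology | None = None
                          ) -> float:
    """Energy-model hydrogen-bond score over pairs touching a side chain."""
    model = model or EnergyModel()
    from .energy import HB_IDEAL, HB_WIDTH
    bonds = enumerate_hbonds(structure, ligand_topology)
    tab = _atom_table(structure, include_ligand=True)
    unit_atoms = {}
    total = 0.0
    for (ia, na), (ib, nb) in bonds:
        ua, ub = tab["units"][ia], tab["units"][ib]
        if ua.atoms[na].backbone and ub.atoms[nb].backbone:
            continue
        d = float(np.linalg.norm(ua.coord(na) - ub.coord(nb)))
        total -= model.w_hb * np.exp(-((d - HB_IDEAL) ** 2)
                                     / (2.0 * HB_WIDTH ** 2))
    return total


# ---------------------------------------------------------------------------
# score records
# ---------------------------------------------------------------------------

@dataclass
class ScoreRecord:
    """One design's metric vector; the scorefile holds one line per record."""

    design_id: str
    metrics: dict

    def __getitem__(self, name: str) -> float:
        return self.metrics[name]

    def validate(self) -> None:
        n_sr = len([k for k in self.metrics if k.startswith("SR")
                    and k[2:].isdigit()])
        sr_sum = sum(self.metrics[f"SR{i}"] for i in range(1, n_sr))
        if abs(sr_sum - self.metrics["all_cst"]) > 1e-6:
            raise ValueError("all_cst does not equal the sum of SR1..SRN")


def compute_score_record(structure: Structure, theozyme: Theozyme,
                         ligand_topology: LigandTopology,
                         model: EnergyModel | None = None,
                         design_id: str = "design",
                         cfg: DesignConfig | None = None,
                         apo_rmsds: dict | None = None) -> ScoreRecord:
    """The full Stage-4 metric suite for one model.

    Restraints are excluded from ``total_score``.  Apo-repack RMSDs are
    computed (via ``repack_without_ligand``) when a design config is given
    and not already supplied.
    """
    model = model or EnergyModel()
    energy = model.structure_energy(structure)
    all_cst, per_block = restraint_scores(structure, theozyme, ligand_topology)
    n_blocks = len(theozyme.blocks)
    metrics = {
        "total_score": energy["total"],
        "fa_rep": energy["rep"],
        "hbond_sc": hbond_sidechain_score(structure, model, ligand_topology),
        "all_cst": all_cst,
        "interface_score": interface_score(structure, model),
        "tot_pstat_pm": packing_metric(structure, with_ligand=True),
        "total_nlpstat_pm": packing_metric(structure, with_ligand=False),
    }
    bu, bu_cat = count_buried_unsat(structure, ligand_topology)
    metrics["tot_burunsat_pm"] = bu
    metrics["cat_burunsat_pm"] = bu_cat
    nl, nl_cat = count_nonlocal_contacts(structure)
    metrics["tot_nlcontacts_pm"] = nl
    metrics["cat_nlcontacts_pm"] = nl_cat
    hb, hb_cat = count_hbonds(structure, ligand_topology)
    metrics["hbonds"] = hb
    metrics["cat_hbonds"] = hb_cat
    for i, score in enumerate(per_block, start=1):
        metrics[f"SR{i}"] = score
    lig_mediated = [s for b, s in zip(theozyme.blocks, per_block)
                    if any(m.is_ligand for m in (b.map1, b.map2))]
    metrics[f"SR{n_blocks + 1}"] = float(sum(lig_mediated))
    if apo_rmsds is None and cfg is not None:
        _, apo_rmsds, mean_rmsd = repack_without_ligand(
            structure, theozyme, ligand_topology, cfg, model)
        metrics["active_site_rmsd"] = mean_rmsd
    elif apo_rmsds is not None:
        metrics["active_site_rmsd"] = float(np.mean(list(apo_rmsds.values()))) \
            if apo_rmsds else 0.0
    else:
        apo_rmsds = {}
        metrics["active_site_rmsd"] = 0.0
    for i in range(1, n_blocks + 1):
        metrics[f"SR{i}_rmsd"] = float(apo_rmsds.get(i, 0.0))
    record = ScoreRecord(design_id=design_id, metrics=metrics)
    record.validate()
    return record


def score_reference(structure: Structure, theozyme: Theozyme,
                    ligand_topology: LigandTopology,
                    cfg: DesignConfig | None = None,
                    model: EnergyModel | None = None,
                    design_id: str = "reference") -> ScoreRecord:
    """Repack + minimise a known-good structure under the same restraints,
    then run the metric suite — the benchmark designs are compared against.
    """
    cfg = cfg or DesignConfig()
    model = model or EnergyModel()
    for bi in range(1, len(theozyme.blocks) + 1):
        if bi not in {i for i, _ in structure.catalytic_residues()}:
            raise ValueError(f"reference lacks catalytic residue for block {bi}")
    shell = detect_design_shell(structure, cfg)
    task = task_from_shell(structure, shell)
    repack_task = PackerTask(entries={
        k: (("repackable", (structure.find(*k).name3,))
            if mode in ("designable", "repackable", "catalytic")
            else (mode, allowed))
        for k, (mode, allowed) in task.entries.items()})
    st = pack_structure(structure, repack_task, cfg, model, theozyme,
                        ligand_topology,
                        rng=np.random.default_rng(cfg.seed + 7))
    if cfg.cst_min:
        dof = _DofModel(st, theozyme, ligand_topology, cfg, model,
                        set(repack_task.movable()))
        st, _ = _minimise(dof, include_atr=True)
    return compute_score_record(st, theozyme, ligand_topology, model,
                                design_id, cfg)


# ---------------------------------------------------------------------------
# scorefile io
# ---------------------------------------------------------------------------

def write_scorefile(records: list, path) -> None:
    """Whitespace-delimited table: header + one line per design."""
    if not records:
        Path(path).write_text("design_id\n")
        return
    columns = list(records[0].metrics)
    for r in records:
        if list(r.metrics) != columns:
            raise ValueError("records do not share a column set")
    df = pd.DataFrame([{"design_id": r.design_id, **r.metrics}
                       for r in records])
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_scorefile(path) -> list:
    df = pd.read_csv(path, sep=r"\s+")
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        design_id = str(d.pop("design_id"))
        out.append(ScoreRecord(design_id=design_id, metrics=d))
    return out


# ---------------------------------------------------------------------------
# cutoffs
# ---------------------------------------------------------------------------

@dataclass
class CutoffSpec:
    """metric comparator threshold, e.g. ('all_cst', '<', 6.5)."""

    metric: str
    comparator: str
    threshold: float

    def passes(self, record: ScoreRecord) -> bool:
        if self.metric not in record.metrics:
            raise KeyError(f"unknown metric {self.metric!r}")
        v = record.metrics[self.metric]
        return v < self.threshold if self.comparator == "<" \
            else v > self.threshold

    def __post_init__(self):
        if self.comparator not in ("<", ">"):
            raise ValueError("comparator must be '<' or '>'")


def parse_cutoffs(text) -> list:
    """One cutoff per line: '<metric> <comparator> <threshold>'."""
    if hasattr(text, "read"):
        text = text.read()
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) != 3:
            raise ValueError(f"cutoff line {lineno}: need 'metric cmp value'")
        out.append(CutoffSpec(tok[0], tok[1], float(tok[2])))
    return out


def default_cutoffs(reference: ScoreRecord | None = None) -> list:
    """The standard selection thresholds.

    Site quality is absolute (restraint scores, apo-repack RMSDs); scaffold
    integrity (total score, buried unsatisfied polars, non-local contacts,
    packing) is expressed relative to a repacked reference when one is
    given.
    """
    cuts = [
        CutoffSpec("all_cst", "<", 6.5),
        CutoffSpec("SR1", "<", 1.2),
        CutoffSpec("SR2", "<", 1.0),
        CutoffSpec("SR3", "<", 2.3),
        CutoffSpec("active_site_rmsd", "<", 0.5),
        CutoffSpec("SR1_rmsd", "<", 0.5),
        CutoffSpec("SR2_rmsd", "<", 0.5),
        CutoffSpec("SR3_rmsd", "<", 0.5),
    ]
    rel = [("total_score", "<", 0.0), ("tot_burunsat_pm", "<", 5.0),
           ("tot_nlcontacts_pm", ">", -2.0), ("tot_pstat_pm", ">", -0.05)]
    for metric, cmp_, thr in rel:
        base = reference.metrics.get(metric, 0.0) if reference else 0.0
        cuts.append(CutoffSpec(metric, cmp_, thr + base))
    return cuts


def filter_designs(records: list, cutoffs: list) -> tuple:
    """(records passing every cutoff, per-cutoff pass counts).

    With no cutoffs every record passes.
    """
    counts = {f"{c.metric} {c.comparator} {c.threshold:g}": 0 for c in cutoffs}
    passing = []
    for r in records:
        ok = True
        for c in cutoffs:
            if c.passes(r):
                counts[f"{c.metric} {c.comparator} {c.threshold:g}"] += 1
            else:
                ok = False
        if ok:
            passing.append(r)
    return passing, counts
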