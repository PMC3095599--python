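"""Internal-coordinate geometry for constraint measurement and atom placement.

The six geometric parameters that relate two constrained residues are measured
and rebuilt here: one distance, two bond angles and three dihedrals, defined
over an ordered atom triple on each partner (atom1, atom2, atom3, where atom2
is the base of atom1 and atom3 the base of atom2):

    distanceAB   |Res1:Atom1 - Res2:Atom1|
    angle_A      Res1:Atom2 - Res1:Atom1 - Res2:Atom1
    angle_B      Res1:Atom1 - Res2:Atom1 - Res2:Atom2
    torsion_A    Res1:Atom3 - Res1:Atom2 - Res1:Atom1 - Res2:Atom1
    torsion_AB   Res1:Atom2 - Res1:Atom1 - Res2:Atom1 - Res2:Atom2
    torsion_B    Res1:Atom1 - Res2:Atom1 - Res2:Atom2 - Res2:Atom3

Restraint violations are scored with a flat-bottomed harmonic: zero inside the
stated tolerance, k*(delta - xtol)^2 outside, where delta for angular
parameters is the minimal deviation to any periodic copy of the ideal value.
All angles are degrees, distances Angstrom.  The low-level vector routines
broadcast over leading array dimensions so callers can evaluate sample grids
in one shot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

# sin(angle) below this is treated as degenerate (collinear/coincident input)
COLLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised for coincident or collinear reference atoms."""


# ---------------------------------------------------------------------------
# low-level vector routines (broadcast over leading dimensions)
# ---------------------------------------------------------------------------

def _norm(v):
    return np.linalg.norm(v, axis=-1)


def _unit(v, *, what="vector"):
    n = _norm(v)
    if np.any(n < COLLINEAR_TOL):
        raise DegenerateGeometryError(f"degenerate {what}: zero-length direction")
    return v / n[..., None]


def distance(p0, p1):
    return _norm(np.asarray(p1, float) - np.asarray(p0, float))


def angle(p0, p1, p2):
    """Bond angle p0-p1-p2 in degrees, in [0, 180]."""
    u = _unit(np.asarray(p0, float) - np.asarray(p1, float), what="angle arm")
    w = _unit(np.asarray(p2, float) - np.asarray(p1, float), what="angle arm")
    c = np.clip(np.sum(u * w, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def dihedral(p0, p1, p2, p3):
    """Signed dihedral p0-p1-p2-p3 in degrees, in [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1, what="dihedral axis")
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1)[..., None] * b1
    w = b2 - np.sum(b2 * b1, axis=-1)[..., None] * b1
    if np.any(_norm(v) < COLLINEAR_TOL) or np.any(_norm(w) < COLLINEAR_TOL):
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    out = np.degrees(np.arctan2(y, x))
    return np.where(out >= 180.0, out - 360.0, out)


def place_atom(p1, p2, p3, d, theta, phi):
    """Place a new atom q from three reference atoms plus internal coordinates.

    q satisfies |q - p3| = d, angle(p2, p3, q) = theta and
    dihedral(p1, p2, p3, q) = phi (NeRF construction).  Broadcasts over
    leading dimensions of all six arguments.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    d, theta, phi = np.broadcast_arrays(
        np.asarray(d, float), np.radians(np.asarray(theta, float)),
        np.radians(np.asarray(phi, float)))

    bc = _unit(p3 - p2, what="placement axis p2->p3")
    ab = p2 - p1
    n_raw = np.cross(ab, bc)
    if np.any(_norm(n_raw) < COLLINEAR_TOL):
        raise DegenerateGeometryError("collinear reference atoms for placement")
    n = _unit(n_raw)
    m = np.cross(n, bc)

    local = np.stack(
        [
            -d * np.cos(theta),
            d * np.sin(theta) * np.cos(phi),
            d * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    return (
        p3
        + local[..., 0:1] * bc
        + local[..., 1:2] * m
        + local[..., 2:3] * n
    )


def wrap_degrees(x, period=360.0):
    """Wrap angle(s) into [0, period)."""
    return np.mod(x, period)


def wrap_signed(x):
    """Wrap angle(s) into [-180, 180)."""
    return np.mod(np.asarray(x, float) + 180.0, 360.0) - 180.0


def periodic_delta(x, x0, per):
    """Minimal absolute deviation of x from any periodic copy x0 + m*per.

    Result lies in [0, per/2].
    """
    if np.any(np.asarray(per) <= 0):
        raise ValueError("periodicity must be positive")
    d = np.mod(np.asarray(x, float) - x0, per)
    return np.minimum(d, per - d)


def superpose_transform(fixed, moving):
    """Rigid transform (R, t) minimising RMSD of moving onto fixed (Kabsch).

    Returns (R, t) with fixed ~= moving @ R.T + t.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return R, t


# ---------------------------------------------------------------------------
# parameter tuples
# ---------------------------------------------------------------------------

PARAM_NAMES = ("distanceAB", "angle_A", "angle_B",
               "torsion_A", "torsion_AB", "torsion_B")

ANGULAR_PARAMS = PARAM_NAMES[1:]


@dataclass(frozen=True)
class ParamTuple:
    """The six internal coordinates relating two constrained atom triples."""

    distanceAB: float
    angle_A: float
    angle_B: float
    torsion_A: float
    torsion_AB: float
    torsion_B: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def swapped(self) -> "ParamTuple":
        """The same geometry with partners 1 and 2 exchanged.

        Swapping exchanges angle_A with angle_B and torsion_A with torsion_B;
        distanceAB and torsion_AB are symmetric.
        """
        return ParamTuple(
            distanceAB=self.distanceAB,
            angle_A=self.angle_B,
            angle_B=self.angle_A,
            torsion_A=self.torsion_B,
            torsion_AB=self.torsion_AB,
            torsion_B=self.torsion_A,
        )


def measure_params(res1_triple, res2_triple) -> ParamTuple:
    """Measure the six constraint parameters between two atom triples.

    Each triple is (atom1, atom2, atom3) coordinates, shape (3, 3).
    """
    a1, a2, a3 = np.asarray(res1_triple, float)
    b1, b2, b3 = np.asarray(res2_triple, float)
    if distance(a1, b1) < COLLINEAR_TOL:
        raise DegenerateGeometryError("Res1:Atom1 and Res2:Atom1 coincide")
    return ParamTuple(
        distanceAB=float(distance(a1, b1)),
        angle_A=float(angle(a2, a1, b1)),
        angle_B=float(angle(a1, b1, b2)),
        torsion_A=float(dihedral(a3, a2, a1, b1)),
        torsion_AB=float(dihedral(a2, a1, b1, b2)),
        torsion_B=float(dihedral(a1, b1, b2, b3)),
    )


def build_partner2_triple(res1_triple, sample: ParamTuple,
                          bond12: float, bond23: float, angle123: float):
    """Construct Res2's atom triple from Res1's triple and a parameter sample.

    ``bond12``, ``bond23`` and ``angle123`` are partner 2's internal geometry
    (atom1-atom2 and atom2-atom3 bond lengths, atom1-atom2-atom3 angle).
    Returns an array (3, 3): the coordinates of Res2 atoms 1-3.
    """
    a1, a2, a3 = np.asarray(res1_triple, float)
    b1 = place_atom(a3, a2, a1, sample.distanceAB, sample.angle_A, sample.torsion_A)
    b2 = place_atom(a2, a1, b1, bond12, sample.angle_B, sample.torsion_AB)
    b3 = place_atom(a1, b1, b2, bond23, angle123, sample.torsion_B)
    return np.stack([b1, b2, b3])


# ---------------------------------------------------------------------------
# restraint penalty
# ---------------------------------------------------------------------------

def penalty(x, param) -> float:
    """Flat-bottomed (periodic) harmonic restraint penalty for one parameter.

    Zero whenever the deviation from the nearest periodic copy of x0 is at or
    below xtol (the tolerance boundary itself satisfies the restraint), and
    k*(delta - xtol)^2 beyond it.  ``param`` needs attributes
    name/x0/xtol/k/fourth (a ConstraintParam works).
    """
    if param.name == "distanceAB":
        delta = np.abs(np.asarray(x, float) - param.x0)
    else:
        delta = periodic_delta(x, param.x0, param.fourth)
    excess = np.maximum(0.0, delta - param.xtol)
    return param.k * excess ** 2


def within_tolerance(x, param) -> bool:
    """True when x satisfies the parameter's flat bottom exactly."""
    if param.name == "distanceAB":
        delta = np.abs(np.asarray(x, float) - param.x0)
    else:
        delta = periodic_delta(x, param.x0, param.fourth)
    return bool(np.all(delta <= param.xtol))


def block_score(block, coords1, coords2, triples1=None, triples2=None):
    """Total restraint penalty of one constraint block for realised geometry.

    ``coordsN`` maps atom name -> xyz for partner N.  ``triplesN`` is the list
    of candidate atom-name triples for that partner (from
    ``resolve_atom_triples``); by-name maps default to their single stated
    triple.  With ambiguous (by-type) triples the minimum total over all
    combinations is returned, with the per-parameter breakdown of the best
    combination.

    Returns ``(score, breakdown)``; unresolvable triples give ``(inf, {})``.
    """
    if triples1 is None:
        triples1 = [tuple(block.map1.names)] if block.map1.mode == "by_name" else []
    if triples2 is None:
        triples2 = [tuple(block.map2.names)] if block.map2.mode == "by_name" else []
    best = (np.inf, {})
    for t1 in triples1:
        if any(name not in coords1 for name in t1):
            continue
        c1 = np.stack([np.asarray(coords1[name], float) for name in t1])
        for t2 in triples2:
            if any(name not in coords2 for name in t2):
                continue
            c2 = np.stack([np.asarray(coords2[name], float) for name in t2])
            measured = measure_params(c1, c2).as_dict()
            breakdown = {
                name: float(penalty(measured[name], p))
                for name, p in block.params.items()
            }
            total = sum(breakdown.values())
            if total < best[0]:
                best = (total, breakdown)
    return best


# ---------------------------------------------------------------------------
# 6D pose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose6D:
    """A ligand placement: 3 Euclidean + 3 Euler (z-x-z) coordinates.

    Euler angles are wrapped to [0, 360).
    """

    tx: float
    ty: float
    tz: float
    e1: float
    e2: float
    e3: float

    def as_array(self):
        return np.array([self.tx, self.ty, self.tz, self.e1, self.e2, self.e3])


def frame_from_triple(triple):
    """Right-handed orthonormal frame from three atoms by Gram-Schmidt.

    Origin at atom 1; x along atom1->atom2; atom3 fixes the xy-plane.
    Returns (origin, R) with frame axes as the columns of R.
    """
    a1, a2, a3 = np.asarray(triple, float)
    e1 = _unit(a2 - a1, what="frame x-axis")
    u = a3 - a1
    u = u - np.dot(u, e1) * e1
    if _norm(u) < COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear frame atoms")
    e2 = _unit(u)
    e3 = np.cross(e1, e2)
    return a1, np.stack([e1, e2, e3], axis=-1)


def pose_from_frame_triple(triple) -> Pose6D:
    """6D pose of a rigid body given its three frame atoms.

    At the z-x-z degeneracy (e2 = 0 or 180) the third angle is fixed to 0,
    scipy's deterministic convention.
    """
    import warnings
    origin, R = frame_from_triple(triple)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        e1, e2, e3 = Rotation.from_matrix(R).as_euler("zxz", degrees=True)
    return Pose6D(
        tx=float(origin[0]), ty=float(origin[1]), tz=float(origin[2]),
        e1=float(wrap_degrees(e1)), e2=float(wrap_degrees(e2)),
        e3=float(wrap_degrees(e3)),
    )
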