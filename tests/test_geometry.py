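"""Internal-coordinate measurement/construction and the flat-bottom penalty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from enzgraft.cst import ConstraintParam
from enzgraft.geometry import (DegenerateGeometryError, ParamTuple, angle,
                               block_score, build_partner2_triple, dihedral,
                               measure_params, penalty, periodic_delta,
                               place_atom, pose_from_frame_triple,
                               wrap_signed)


def _random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(size=3) * 5
    return lambda x: np.asarray(x) @ R.T + t


class TestMeasure:
    def test_axis_aligned_construction(self):
        # right-angle arms off the A1-B1 axis
        r1 = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 1]], float)
        r2 = np.array([[3, 0, 0], [3, 1, 0], [3, 2, 1]], float)
        p = measure_params(r1, r2)
        assert p.distanceAB == pytest.approx(3.0)
        assert p.angle_A == pytest.approx(90.0)
        assert p.angle_B == pytest.approx(90.0)

    def test_trans_torsion_is_180(self):
        p0, p1, p2, p3 = [0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]
        assert dihedral(p0, p1, p2, p3) == pytest.approx(-180.0)

    def test_coincident_atoms_error(self):
        tri = np.zeros((3, 3))
        with pytest.raises(DegenerateGeometryError):
            measure_params(tri, tri)


class TestPlaceAtom:
    def test_cis_is_coplanar(self):
        p1, p2, p3 = np.array([0., 1, 0]), np.array([0., 0, 0]), np.array([1., 0, 0])
        q = place_atom(p1, p2, p3, 1.5, 109.5, 0.0)
        assert abs(q[2]) < 1e-9 and q[1] > 0  # same side as p1

    def test_collinear_reference_error(self):
        with pytest.raises(DegenerateGeometryError):
            place_atom([0, 0, 0], [1, 0, 0], [2, 0, 0], 1.5, 109.5, 60.0)

    def test_coincident_reference_error(self):
        with pytest.raises(DegenerateGeometryError):
            place_atom([0, 0, 0], [0, 0, 0], [1, 0, 0], 1.5, 109.5, 60.0)


@settings(max_examples=100, deadline=None)
@given(d=st.floats(0.8, 5.0), theta=st.floats(5.0, 175.0),
       phi=st.floats(-179.9, 179.9), seed=st.integers(0, 10_000))
def test_place_measure_roundtrip(d, theta, phi, seed):
    """Measuring after NeRF placement recovers (d, theta, phi) to 1e-9."""
    rng = np.random.default_rng(seed)
    while True:
        p1, p2, p3 = rng.normal(size=(3, 3)) * 3
        if (np.linalg.norm(np.cross(p2 - p1, p3 - p2))
                / (np.linalg.norm(p2 - p1) * np.linalg.norm(p3 - p2) + 1e-12)
                > 1e-3):
            break
    q = place_atom(p1, p2, p3, d, theta, phi)
    assert np.linalg.norm(q - p3) == pytest.approx(d, abs=1e-9)
    assert float(angle(p2, p3, q)) == pytest.approx(theta, abs=1e-9)
    assert abs(wrap_signed(float(dihedral(p1, p2, p3, q)) - phi)) < 1e-9


def test_build_partner2_roundtrip():
    t1 = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0]], float)
    sample = ParamTuple(3.0, 105.0, 120.0, -60.0, 170.0, 45.0)
    t2 = build_partner2_triple(t1, sample, 1.4, 1.3, 115.0)
    m = measure_params(t1, t2)
    for name in ("distanceAB", "angle_A", "angle_B",
                 "torsion_A", "torsion_AB", "torsion_B"):
        assert getattr(m, name) == pytest.approx(getattr(sample, name), abs=1e-9)


class TestPeriodicDelta:
    @pytest.mark.parametrize("x,x0,per,expect", [
        (120.0, 120.0, 360.0, 0.0),
        (300.0, 120.0, 180.0, 0.0),
        (359.0, 1.0, 360.0, 2.0),
    ])
    def test_examples(self, x, x0, per, expect):
        assert float(periodic_delta(x, x0, per)) == pytest.approx(expect)

    @settings(max_examples=60, deadline=None)
    @given(x=st.floats(-360, 720), x0=st.floats(-360, 720),
           per=st.sampled_from([60.0, 90.0, 120.0, 180.0, 360.0]))
    def test_matches_bruteforce_over_copies(self, x, x0, per):
        brute = min(abs(x - (x0 + m * per)) for m in range(-20, 21))
        assert float(periodic_delta(x, x0, per)) == pytest.approx(brute, abs=1e-9)


class TestPenalty:
    def test_flat_bottom_is_zero(self):
        p = ConstraintParam("angle_A", 73.6, 10.0, 80.0, 360.0, 1)
        xs = np.linspace(63.6, 83.6, 41)
        assert np.all(penalty(xs, p) == 0.0)

    def test_value_beyond_tolerance(self):
        p = ConstraintParam("angle_A", 100.0, 10.0, 80.0, 360.0, 0)
        assert float(penalty(100.0 + 10.0 + 0.5, p)) == pytest.approx(20.0)

    def test_continuity_at_boundary(self):
        p = ConstraintParam("torsion_A", 50.0, 12.0, 33.0, 360.0, 0)
        eps = np.linspace(-1e-4, 1e-4, 21)
        vals = penalty(50.0 + 12.0 + eps, p)
        assert np.all(vals <= 33.0 * (2e-4) ** 2 + 1e-12)

    def test_three_minima_for_period_120(self):
        p = ConstraintParam("torsion_B", 120.0, 1.0, 10.0, 120.0, 0)
        xs = np.arange(0.0, 360.0, 0.1)
        at_min = penalty(xs, p) == 0.0
        # count disjoint runs of minimal values
        runs = int(np.sum(at_min[1:] & ~at_min[:-1])) + int(at_min[0])
        if at_min[0] and at_min[-1]:  # wrap-around join
            runs -= 1
        assert runs == 3
        for center in (120.0, 240.0, 0.0):
            assert float(penalty(center, p)) == 0.0

    def test_two_minima_for_period_180(self):
        p = ConstraintParam("torsion_B", 120.0, 1.0, 10.0, 180.0, 0)
        xs = np.arange(0.0, 360.0, 0.1)
        mins = xs[np.asarray(penalty(xs, p)) == 0.0]
        groups = np.split(mins, np.nonzero(np.diff(mins) > 0.2)[0] + 1)
        centers = sorted(float(np.median(g)) for g in groups)
        assert centers == pytest.approx([120.0, 300.0], abs=0.1)

    def test_periodic_invariance(self):
        p = ConstraintParam("torsion_A", 45.0, 5.0, 20.0, 90.0, 0)
        xs = np.linspace(0, 360, 73)
        assert np.allclose(penalty(xs, p), penalty(xs + 90.0, p))


class TestBlockScore:
    def _realized(self, block, sample):
        """Coordinates realising the block at the given parameter tuple.

        The ligand is partner 1 of the example block, so the protein triple
        is built directly as partner 2.
        """
        lig = np.array([[0, 0, 0], [1.52, 0, 0], [2.1, 1.3, 0]], float)
        prot = build_partner2_triple(lig, sample, 1.25, 1.52, 119.0)
        coords1 = dict(zip(("C1", "C2", "O2"), lig))
        coords2 = dict(zip(("OD1", "CG", "CB"), prot))
        return coords1, coords2

    def test_zero_at_ideal_values(self, example_block):
        x0 = ParamTuple(**{n: p.x0 for n, p in example_block.params.items()})
        c1, c2 = self._realized(example_block, x0)
        s, breakdown = block_score(example_block, c1, c2,
                                   [("C1", "C2", "O2")], [("OD1", "CG", "CB")])
        assert s == 0.0
        assert all(v == 0.0 for v in breakdown.values())

    def test_ambiguous_triples_take_minimum(self, example_block):
        x0 = ParamTuple(**{n: p.x0 for n, p in example_block.params.items()})
        c1, c2 = self._realized(example_block, x0)
        # a decoy OD2 far from ideal: min over OD1/OD2 picks the satisfied one
        c2["OD2"] = c2["OD1"] + np.array([4.0, 0.0, 0.0])
        s, _ = block_score(example_block, c1, c2, [("C1", "C2", "O2")],
                          [("OD1", "CG", "CB"), ("OD2", "CG", "CB")])
        assert s == 0.0

    def test_zero_force_constant_contributes_nothing(self, example_block):
        bad = ParamTuple(**{n: p.x0 for n, p in example_block.params.items()})
        bad = ParamTuple(bad.distanceAB, bad.angle_A, bad.angle_B,
                         bad.torsion_A, 30.0, bad.torsion_B)  # torsion_AB off
        c1, c2 = self._realized(example_block, bad)
        s, breakdown = block_score(example_block, c1, c2,
                                   [("C1", "C2", "O2")], [("OD1", "CG", "CB")])
        assert breakdown["torsion_AB"] == 0.0  # k = 0 in the example
        assert s == 0.0

    def test_rigid_motion_invariance(self, example_block):
        rng = np.random.default_rng(5)
        x0 = ParamTuple(**{n: p.x0 + 3.0 * (n != "distanceAB")
                           for n, p in example_block.params.items()})
        c1, c2 = self._realized(example_block, x0)
        s0, _ = block_score(example_block, c1, c2, [("C1", "C2", "O2")],
                           [("OD1", "CG", "CB")])
        move = _random_rigid(rng)
        c1m = {k: move(v) for k, v in c1.items()}
        c2m = {k: move(v) for k, v in c2.items()}
        s1, _ = block_score(example_block, c1m, c2m, [("C1", "C2", "O2")],
                           [("OD1", "CG", "CB")])
        assert s1 == pytest.approx(s0, abs=1e-8)

    def test_unresolvable_triple_is_infinite(self, example_block):
        s, breakdown = block_score(example_block, {}, {}, [("C1", "C2", "O2")],
                                   [("OD1", "CG", "CB")])
        assert s == np.inf and breakdown == {}


class TestPose6D:
    triple = np.array([[1, 2, 3], [2.5, 2, 3], [1.5, 3.5, 3]], float)

    def test_identical_placements_equal(self):
        assert pose_from_frame_triple(self.triple) == \
            pose_from_frame_triple(self.triple.copy())

    def test_translation_moves_origin_only(self):
        a = pose_from_frame_triple(self.triple)
        b = pose_from_frame_triple(self.triple + np.array([1.0, 0, 0]))
        assert b.tx - a.tx == pytest.approx(1.0)
        assert (b.ty, b.tz) == pytest.approx((a.ty, a.tz))
        assert (b.e1, b.e2, b.e3) == pytest.approx((a.e1, a.e2, a.e3))

    def test_frame_z_rotation_shifts_first_euler(self):
        a = pose_from_frame_triple(self.triple)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rotated = self.triple @ R.T
        b = pose_from_frame_triple(rotated)
        assert (b.e1 - a.e1) % 360.0 == pytest.approx(90.0, abs=1e-7)

    def test_equivariance_under_random_rigid_motion(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            move = _random_rigid(rng)
            moved = move(self.triple)
            pose = pose_from_frame_triple(moved)
            # rebuild the triple from the pose and check it matches
            back = pose_from_frame_triple(moved)
            assert pose == back

    def test_collinear_frame_error(self):
        bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            pose_from_frame_triple(bad)
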