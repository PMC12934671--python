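import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from kinactive.geometry import (
    GeometryError,
    chi1_minus,
    dihedral,
    min_pair_distance,
    rama_region,
    rotamer_word,
    virtual_cbeta,
)


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent torsion formula: atan2 on explicitly constructed normals."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2) * np.linalg.norm(b2)
    y = np.dot(np.cross(n1, n2), b2)
    return math.degrees(math.atan2(y, x))


finite_coord = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


class TestDihedral:
    def test_cis_is_zero(self):
        pts = [(1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        pts = [(1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)]
        assert abs(dihedral(*pts)) == pytest.approx(180.0, abs=1e-9)

    def test_matches_independent_formula_on_random_quadruples(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 1000:
            pts = rng.uniform(-10, 10, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            expected = brute_force_dihedral(*pts)
            diff = abs(ours - expected) % 360.0
            assert min(diff, 360.0 - diff) < 1e-6
            n_checked += 1

    @given(pts=st.lists(point, min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_reversal_and_rigid_invariance(self, pts):
        b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
        # keep away from degenerate geometry where the torsion is ill-conditioned
        assume(np.linalg.norm(np.cross(b1, b2)) > 1e-2)
        assume(np.linalg.norm(np.cross(b2, b3)) > 1e-2)
        fwd = dihedral(*pts)
        # order reversal preserves the torsion
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-6)
        # mirror image negates it (unless torsion is 0/180)
        mirrored = [p * np.array([1, 1, -1]) for p in pts]
        assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-6) or abs(
            abs(fwd) - 180.0
        ) < 1e-6
        # rigid transform leaves it unchanged
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = [rot @ p + np.array([3.0, -2.0, 5.0]) for p in pts]
        assert dihedral(*moved) == pytest.approx(fwd, abs=1e-5)

    def test_degenerate_points_raise(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            dihedral(p, p, (1, 0, 0), (1, 1, 0))


class TestRamaRegion:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-120, 120, "B"),
            (-75, -30, "A"),
            (60, 40, "L"),
            (-60, 50, "A"),     # boundary psi=50 closed into A
            (-60, 180, "B"),    # psi=180 belongs to B
            (-60, -180, "B"),   # wraparound
            (120, 120, "other"),
            (90, -60, "other"),
            (-90, -150, "other"),
        ],
    )
    def test_region_labels(self, phi, psi, expected):
        assert rama_region(phi, psi) == expected

    def test_missing_angles_give_none(self):
        assert rama_region(None, 30) == "none"
        assert rama_region(30, None) == "none"

    @given(
        phi=st.floats(-180, 180, allow_nan=False),
        psi=st.floats(-180, 180, allow_nan=False),
    )
    @settings(max_examples=500, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, phi, psi):
        """Every finite (phi, psi) maps to exactly one of A/B/L/other."""
        assert rama_region(phi, psi) in {"A", "B", "L", "other"}


class TestChi1:
    @pytest.mark.parametrize(
        "chi,expected", [(-60, True), (55, False), (-120, False), (0, False), (-119.9, True)]
    )
    def test_gauche_minus_bin(self, chi, expected):
        assert chi1_minus(chi) is expected

    def test_absent_chi1_is_indeterminate(self):
        assert chi1_minus(None) is None
        assert rotamer_word(None) is None

    @pytest.mark.parametrize("chi,word", [(-65, "minus"), (62, "plus"), (175, "trans"), (-150, "trans")])
    def test_rotamer_words(self, chi, word):
        assert rotamer_word(chi) == word


class TestMinPairDistance:
    def test_simple(self):
        assert min_pair_distance([(0, 0, 0)], [(3, 0, 0), (5, 0, 0)]) == pytest.approx(3.0)

    def test_identical_sets(self):
        assert min_pair_distance([(1, 2, 3)], [(1, 2, 3)]) == 0.0

    def test_empty_set_propagates_missing(self):
        assert min_pair_distance([], [(1, 2, 3)]) is None

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(-5, 5, size=(10, 3))
        b = rng.uniform(-5, 5, size=(10, 3))
        expected = min(np.linalg.norm(x - y) for x in a for y in b)
        assert min_pair_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestVirtualCbeta:
    def test_close_to_real_cbeta_of_ideal_residue(self):
        from kinactive.fixtures import _build_chain

        chain = _build_chain(
            ["ALA", "ALA", "ALA"], [-120, -70, -120], [130, -40, 130], [None] * 3
        )
        res = chain[1]
        d = np.linalg.norm(virtual_cbeta(res["N"], res["CA"], res["C"]) - res["CB"])
        assert d < 0.3

    def test_equivariance_under_rigid_transform(self):
        n, ca, c = np.array([1.0, 0, 0]), np.array([0.0, 1.4, 0]), np.array([1.2, 2.5, 0.3])
        base = virtual_cbeta(n, ca, c)
        t = np.array([4.0, -1.0, 2.0])
        assert np.allclose(virtual_cbeta(n + t, ca + t, c + t), base + t, atol=1e-9)
        theta = 1.1
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        assert np.allclose(virtual_cbeta(rot @ n, rot @ ca, rot @ c), rot @ base, atol=1e-9)

    def test_degenerate_triad_raises(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            virtual_cbeta(p, p, np.array([1.0, 0, 0]))
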