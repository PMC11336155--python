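"""Deformation gradients, Green strain, incremental mechanics, landmarks."""

from itertools import combinations

import numpy as np
import pytest

from dermakin import (
    green_strain,
    isoparametric_F2d,
    landmark_value,
    largest_tetrahedron,
    mechanics_curve,
    tabulate_landmarks,
    tetra_F3d,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestIsoparametricF2d:
    def test_identity(self):
        assert np.allclose(isoparametric_F2d(UNIT_SQUARE, UNIT_SQUARE), np.eye(2))

    def test_affine_map_reproduced_exactly(self):
        A = np.array([[1.1, 0.05], [0.0, 0.9]])
        b = np.array([0.3, -0.2])
        deformed = UNIT_SQUARE @ A.T + b
        assert np.allclose(isoparametric_F2d(UNIT_SQUARE, deformed), A, atol=1e-10)

    def test_uniaxial_stretch_green_strain(self):
        deformed = UNIT_SQUARE * np.array([1.2, 1.0])
        F = isoparametric_F2d(UNIT_SQUARE, deformed)
        eps, _, _ = green_strain(F)
        assert eps[0, 0] == pytest.approx(0.5 * (1.2**2 - 1))  # 0.22
        assert eps[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_node_order_independence(self):
        A = np.array([[1.05, 0.02], [-0.01, 0.93]])
        perm = [2, 0, 3, 1]
        assert np.allclose(
            isoparametric_F2d(UNIT_SQUARE[perm], UNIT_SQUARE[perm] @ A.T), A, atol=1e-10
        )

    def test_overdetermined_least_squares(self):
        rng = np.random.default_rng(0)
        ref = rng.random((7, 2)) * 5
        A = np.array([[1.1, 0.0], [0.05, 0.9]])
        assert np.allclose(isoparametric_F2d(ref, ref @ A.T + 2.0), A, atol=1e-10)

    def test_collinear_markers_rejected(self):
        line = np.stack([np.arange(4.0), np.arange(4.0)], axis=1)
        with pytest.raises(ValueError):
            isoparametric_F2d(line, line)


class TestGreenStrain:
    def test_identity_gives_zero(self):
        eps, vals, _ = green_strain(np.eye(3))
        assert np.allclose(eps, 0.0) and np.allclose(vals, 0.0)

    def test_diagonal_closed_form(self):
        eps, vals, _ = green_strain(np.diag([1.1, 0.9, 0.95]))
        assert np.allclose(np.diag(eps), [0.105, -0.095, -0.048750])
        assert np.allclose(vals, [0.105, -0.048750, -0.095])  # descending

    def test_pure_rotation_is_objective(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        eps, _, _ = green_strain(R)
        assert np.allclose(eps, 0.0, atol=1e-12)


class TestMechanicsCurve:
    def test_backward_difference_modulus(self):
        strains = [np.diag([e, 0.0]) for e in (0.0, 0.05, 0.10)]
        recs = mechanics_curve([0.0, 10.0, 30.0], 1.0, strains)
        assert np.isnan(recs[0].modulus) and not recs[0].modulus_defined
        assert recs[1].modulus == pytest.approx(200.0)
        assert recs[2].modulus == pytest.approx(400.0)

    def test_poisson_ratio_formula(self):
        # eps_yy = -0.219 at eps_xx = 0.10 gives nu = 2.19
        recs = mechanics_curve([0.0, 1.0], 1.0, [np.zeros((2, 2)), np.diag([0.10, -0.219])])
        assert recs[1].poisson == pytest.approx(2.19)

    def test_engineering_stress_from_gauge_area(self):
        # 0.1 N over a 2.03 mm x 0.493 mm cross-section is ~99.9 kPa
        area0 = 2.03e-3 * 0.493e-3
        recs = mechanics_curve([0.0, 0.1], area0, [np.zeros((2, 2)), np.diag([0.1, -0.1])])
        assert recs[1].stress == pytest.approx(99.9e3, rel=1e-3)

    def test_zero_strain_increment_flagged_not_infinite(self):
        strains = [np.diag([e, 0.0]) for e in (0.0, 0.05, 0.05)]
        recs = mechanics_curve([0.0, 1.0, 2.0], 1.0, strains)
        assert np.isnan(recs[2].modulus) and not recs[2].modulus_defined


class TestLargestTetrahedron:
    def test_unit_cube_volume_one_third(self):
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        idx = largest_tetrahedron(cube)
        e = (cube[list(idx)][1:] - cube[list(idx)][0]).T
        assert abs(np.linalg.det(e)) / 6 == pytest.approx(1 / 3)

    def test_exactly_four_points_returned_as_is(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert largest_tetrahedron(pts) == (0, 1, 2, 3)

    def test_hull_restricted_matches_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.random((12, 3))
            full = largest_tetrahedron(pts, exhaustive_limit=25)
            hull = largest_tetrahedron(pts, exhaustive_limit=4)
            vol = lambda c: abs(np.linalg.det((pts[list(c)][1:] - pts[list(c)][0]).T)) / 6
            assert vol(full) == pytest.approx(vol(hull), abs=1e-12)

    def test_brute_force_oracle_on_cube(self):
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        vol = lambda c: abs(np.linalg.det((cube[list(c)][1:] - cube[list(c)][0]).T)) / 6
        best = max(vol(c) for c in combinations(range(8), 4))
        assert vol(largest_tetrahedron(cube)) == pytest.approx(best)

    def test_coplanar_cloud_rejected(self):
        pts = np.zeros((6, 3))
        pts[:, :2] = np.random.default_rng(0).random((6, 2))
        with pytest.raises(ValueError):
            largest_tetrahedron(pts)


class TestTetraF3d:
    REF = np.array([[0.0, 0, 0], [10, 0, 0], [0, 12, 0], [0, 0, 8]])

    def test_identity(self):
        st = tetra_F3d(self.REF, self.REF)
        assert np.allclose(st.F, np.eye(3))
        assert st.volume_ratio == pytest.approx(1.0)

    def test_diagonal_stretch_volume_ratio(self):
        F = np.diag([1.1, 0.9, 0.95])
        st = tetra_F3d(self.REF, self.REF @ F.T)
        assert st.volume_ratio == pytest.approx(0.9405)

    def test_translation_invariance(self):
        F = np.array([[1.1, 0.02, 0], [0, 0.9, 0.01], [0, 0, 0.95]])
        st = tetra_F3d(self.REF, self.REF @ F.T + np.array([3.0, -2.0, 5.0]))
        assert np.allclose(st.F, F, atol=1e-12)

    def test_det_equals_tetra_volume_ratio(self):
        rng = np.random.default_rng(5)
        ref = rng.random((4, 3)) * 10
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0:
            F[0] *= -1
        deformed = ref @ F.T
        st = tetra_F3d(ref, deformed)
        vol = lambda t: abs(np.linalg.det((t[1:] - t[0]).T)) / 6
        assert st.volume_ratio == pytest.approx(vol(deformed) / vol(ref), abs=1e-10)

    def test_objectivity_of_green_strain(self):
        F = np.diag([1.15, 0.9, 0.97])
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        a = tetra_F3d(self.REF, self.REF @ F.T)
        b = tetra_F3d(self.REF, self.REF @ (R @ F).T)
        assert np.allclose(a.green, b.green, atol=1e-8)
        assert a.volume_ratio == pytest.approx(b.volume_ratio, abs=1e-8)

    def test_degenerate_reference_rejected(self):
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(ValueError):
            tetra_F3d(flat, flat)


class TestLandmarks:
    def test_linear_interpolation_between_increments(self):
        v = landmark_value([0.08, 0.12], [0.90, 0.80], 0.10)
        assert v == pytest.approx(0.85)

    def test_nearest_increment_for_volume_quantities(self):
        v = landmark_value([0.08, 0.12], [0.90, 0.80], 0.10, interpolate=False)
        assert v in (0.90, 0.80)
        assert landmark_value([0.08, 0.12], [0.90, 0.80], 0.09, interpolate=False) == 0.90

    def test_out_of_range_landmark_missing(self):
        assert landmark_value([0.0, 0.18], [1.0, 2.0], 0.20) is None

    def test_max_modulus_landmark_is_argmax(self):
        strains = [np.diag([e, 0.0]) for e in (0.0, 0.05, 0.10, 0.15)]
        recs = mechanics_curve([0.0, 5.0, 25.0, 40.0], 1.0, strains)
        # E = (100, 400, 300): max at increment 2
        out = tabulate_landmarks(recs, scalars={"nu": [0, 0, 0, 0]})
        assert out["landmarks"]["max E"]["increment"] == 2

    def test_tabulation_interpolates_scalars(self):
        strains = [np.diag([e, -0.5 * e]) for e in (0.0, 0.08, 0.12)]
        recs = mechanics_curve([0.0, 8.0, 12.0], 1.0, strains)
        out = tabulate_landmarks(recs, scalars={"vr": [1.0, 0.90, 0.80], "dv": [0.9, 0.7, 0.5]})
        lm = out["landmarks"]["10% eps_xx"]
        assert lm["vr"] == pytest.approx(0.85)  # interpolated
        assert lm["dv"] in (0.7, 0.5)  # nearest whole volume
        assert out["landmarks"]["20% eps_xx"]["vr"] is None  # out of range
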