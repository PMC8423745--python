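"""Contact solver: queries, penalty layer, friction, frame resolution."""

import numpy as np
import pytest

from occlustress._tri import closest_point_on_triangles
from occlustress.benchmarks import (
    meshed_plane,
    sphere_on_plane_model,
    spherical_cap,
    winkler_sphere_force,
)
from occlustress.contact import (
    build_spatial_index,
    foundation_stiffness,
    friction_traction,
    max_principal_stress,
    penalty_pressure,
    resolve_frame,
    signed_gap,
)
from occlustress.dentition import DentitionModel, MaterialParams, ToothLabelMap
from occlustress.errors import EmptyMeshError, ParameterError, StaleIndexError
from occlustress.kinematics import compose_transform
from occlustress.mesh import SurfaceMesh


def two_triangle_plane():
    verts = np.array(
        [[-1.0, 0, -1], [1.0, 0, -1], [1.0, 0, 1], [-1.0, 0, 1]]
    )
    faces = np.array([[0, 2, 1, -1], [0, 3, 2, -1]])  # normals +y
    return SurfaceMesh(verts, faces)


class TestFoundationStiffness:
    def test_enamel_defaults(self):
        k = foundation_stiffness(MaterialParams())
        assert k == pytest.approx(84000.0 / 0.91 / 2.0, rel=1e-9)
        assert k == pytest.approx(46153.8, abs=0.1)

    def test_nu_zero_limit(self):
        k = foundation_stiffness(
            MaterialParams(poisson_ratio=0.0, foundation_thickness=1.0)
        )
        assert k == pytest.approx(84000.0)

    def test_doubling_h_halves_k(self):
        k1 = foundation_stiffness(MaterialParams(foundation_thickness=1.0))
        k2 = foundation_stiffness(MaterialParams(foundation_thickness=2.0))
        assert k1 == pytest.approx(2.0 * k2)


class TestPenaltyPressure:
    def test_separated_zero(self):
        assert penalty_pressure(0.3, 100.0) == 0.0

    def test_linear_in_penetration(self):
        assert penalty_pressure(-0.01, 100.0) == pytest.approx(1.0)

    def test_monotone(self):
        g = np.array([-0.001, -0.01, -0.1])
        p = penalty_pressure(g, 100.0)
        assert (np.diff(p) > 0).all()

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            penalty_pressure(-0.1, 0.0)


class TestFriction:
    def test_sliding_coulomb(self):
        tau, d = friction_traction(
            np.array([10.0]), np.array([[1.0, 0, 0]]), 0.1
        )
        assert tau[0] == pytest.approx(1.0)
        assert np.allclose(d[0], [-1, 0, 0])

    def test_no_pressure_no_traction(self):
        tau, _ = friction_traction(np.array([0.0]), np.array([[1.0, 0, 0]]), 0.1)
        assert tau[0] == 0.0

    def test_zero_slip_zero_traction(self):
        tau, d = friction_traction(np.array([10.0]), np.zeros((1, 3)), 0.1)
        assert tau[0] == 0.0
        assert np.array_equal(d[0], np.zeros(3))


class TestPrincipalStress:
    @pytest.mark.parametrize(
        "p,tau,expected",
        [(3.0, 2.0, 4.0), (5.0, 0.0, 5.0), (0.0, 1.0, 1.0)],
    )
    def test_mohr_values(self, p, tau, expected):
        assert max_principal_stress(p, tau) == pytest.approx(expected)

    def test_dominates_components(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 10, 50)
        tau = rng.uniform(0, 5, 50)
        s1 = max_principal_stress(p, tau)
        assert (s1 >= np.maximum(p, tau) - 1e-12).all()


class TestSpatialIndex:
    def test_two_triangle_plane_query(self):
        idx = build_spatial_index(two_triangle_plane())
        d, f, _, _ = idx.query(np.array([[0.5, 5.0, -0.5]]))
        assert d[0] == pytest.approx(5.0)
        assert f[0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 200
        a = rng.uniform(-5, 5, (n, 3))
        b = a + rng.normal(0, 1, (n, 3))
        c = a + rng.normal(0, 1, (n, 3))
        verts = np.vstack([a, b, c])
        faces = np.arange(3 * n).reshape(3, n).T
        mesh = SurfaceMesh(verts, faces)
        idx = build_spatial_index(mesh)
        q = rng.uniform(-6, 6, (100, 3))
        d, f, _, _ = idx.query(q)
        qq = np.repeat(q, n, axis=0)
        cp = closest_point_on_triangles(
            qq, np.tile(a, (100, 1)), np.tile(b, (100, 1)), np.tile(c, (100, 1))
        )
        db = np.linalg.norm(qq - cp, axis=1).reshape(100, n)
        assert np.array_equal(f, np.argmin(db, axis=1))
        assert np.abs(d - db.min(axis=1)).max() < 1e-12

    def test_stale_index_detected(self):
        mesh = two_triangle_plane()
        idx = build_spatial_index(mesh)
        mesh.vertices[0, 1] += 1.0
        mesh.bump_version()
        with pytest.raises(StaleIndexError):
            idx.query(np.zeros((1, 3)))

    def test_empty_mesh_rejected(self):
        mesh = SurfaceMesh(np.eye(3), np.empty((0, 4), dtype=int))
        with pytest.raises(EmptyMeshError):
            build_spatial_index(mesh)


class TestSignedGap:
    def test_plane_signs(self):
        idx = build_spatial_index(two_triangle_plane())
        g, _, _ = signed_gap(np.array([[0.0, 1.0, 0.0], [0.0, -0.2, 0.0]]), idx)
        assert g[0] == pytest.approx(1.0)
        assert g[1] == pytest.approx(-0.2)

    def test_far_sentinel(self):
        idx = build_spatial_index(two_triangle_plane())
        g, f, _ = signed_gap(np.array([[0.0, 50.0, 0.0]]), idx, cutoff=5.0)
        assert np.isinf(g[0])
        assert f[0] == -1

    def test_sphere_apex_penetration(self):
        """Sphere apex pressed 0.1 mm past a plane reads -0.100 +/- 0.005."""
        cap = spherical_cap(radius=10.0, cap_extent=2.0, step=0.1)
        plane = meshed_plane(half_extent=3.0, step=0.1)
        idx = build_spatial_index(plane)
        pts = cap.face_centroids() + np.array([0.0, 0.1, 0.0])
        g, _, _ = signed_gap(pts, idx)
        assert abs(g.min() + 0.100) < 0.005


class TestResolveFrame:
    def make_model(self, gap=1.0):
        plane = meshed_plane(half_extent=2.0, step=0.2, y=0.0)
        punch = meshed_plane(half_extent=1.0, step=0.2, y=-gap)
        # punch normals must face the plane above
        punch.faces = punch.faces[:, ::-1]
        return DentitionModel(
            plane,
            punch,
            ToothLabelMap(np.zeros(plane.n_faces, int)),
            ToothLabelMap(np.zeros(punch.n_faces, int)),
            MaterialParams(),
        )

    def test_separated_no_contact(self):
        model = self.make_model(gap=1.0)
        idx = build_spatial_index(model.upper)
        st = resolve_frame(model, compose_transform(0, 0, 0, (0, 0.2, 0)), idx)
        assert st.contact_area == 0.0
        assert st.total_normal_force == 0.0
        assert (st.pressure == 0).all()

    def test_all_far_is_valid_empty_state(self):
        model = self.make_model(gap=20.0)
        idx = build_spatial_index(model.upper)
        st = resolve_frame(model, compose_transform(0, 0, 0, (0, 0, 0)), idx)
        assert (st.nearest_face == -1).all()
        assert st.total_normal_force == 0.0

    def test_complementarity_and_force_sum(self):
        model = self.make_model(gap=0.05)
        idx = build_spatial_index(model.upper)
        st = resolve_frame(
            model, compose_transform(0, 0, 0, (0, 0.1, 0)), idx, k=100.0
        )
        open_gap = np.where(np.isfinite(st.signed_gap), st.signed_gap, 0.0)
        assert np.abs(st.pressure * np.maximum(open_gap, 0.0)).max() == 0.0
        expected = float((st.pressure * st.face_area).sum())
        assert st.total_normal_force == pytest.approx(expected, rel=1e-6)

    def test_friction_cone_holds_while_sliding(self):
        model = self.make_model(gap=0.05)
        idx = build_spatial_index(model.upper)
        prev = resolve_frame(
            model, compose_transform(0, 0, 0, (0, 0.1, 0)), idx, k=100.0
        )
        st = resolve_frame(
            model,
            compose_transform(0, 0, 0, (0.5, 0.1, 0)),
            idx,
            prev_frame=prev,
            dt=0.1,
            k=100.0,
        )
        mu = model.material.friction_coefficient
        assert (st.shear <= mu * st.pressure + 1e-9).all()
        assert st.shear[st.pressure > 0].max() == pytest.approx(
            mu * st.pressure.max(), rel=1e-9
        )

    def test_winkler_sphere_force_small(self):
        """Coarse sphere-on-plane force lands near k*pi*R*delta^2."""
        model = sphere_on_plane_model(radius=10.0, step=0.15, cap_extent=2.0)
        idx = build_spatial_index(model.upper)
        st = resolve_frame(
            model, compose_transform(0, 0, 0, (0, 0.1, 0)), idx, k=100.0
        )
        exact = winkler_sphere_force(100.0, 10.0, 0.1)
        assert st.total_normal_force == pytest.approx(exact, rel=0.05)
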