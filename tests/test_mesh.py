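"""Mesh container, I/O round trips and smoothing."""

import numpy as np
import pytest

from occlustress.errors import (
    DimensionError,
    EmptyMeshError,
    MeshFormatError,
    ParameterError,
)
from occlustress.mesh import SurfaceMesh, load_mesh, save_mesh, smooth_mesh

ASCII_STL = """solid unit
  facet normal 0 0 1
    outer loop
      vertex 0 0 0
      vertex 1 0 0
      vertex 0 1 0
    endloop
  endfacet
endsolid unit
"""


def grid_mesh(n=6, spike=None):
    xs = np.arange(n, dtype=float)
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), np.zeros(X.size), Z.ravel()])
    if spike is not None:
        verts[spike, 1] = 1.0
    idx = np.arange(n * n).reshape(n, n)
    quads = np.column_stack(
        [
            idx[:-1, :-1].ravel(),
            idx[1:, :-1].ravel(),
            idx[1:, 1:].ravel(),
            idx[:-1, 1:].ravel(),
        ]
    )
    return SurfaceMesh(verts, quads)


class TestLoad:
    def test_ascii_stl_unit_triangle(self, tmp_path):
        path = tmp_path / "tri.stl"
        path.write_text(ASCII_STL)
        mesh = load_mesh(path)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1
        assert bool(mesh.is_triangle[0])

    def test_obj_quad_retained(self, tmp_path):
        path = tmp_path / "quad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 1 0 1\nv 0 0 1\nf 1 2 3 4\n")
        mesh = load_mesh(path)
        assert mesh.n_faces == 1
        assert not mesh.is_triangle[0]

    def test_unreadable_names_line(self, tmp_path):
        path = tmp_path / "bad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv x y z\nf 1 2 3\n")
        with pytest.raises(MeshFormatError, match=r"bad\.obj:3"):
            load_mesh(path)

    def test_empty_mesh_rejected(self, tmp_path):
        path = tmp_path / "empty.obj"
        path.write_text("# nothing\n")
        with pytest.raises(EmptyMeshError):
            load_mesh(path)

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "m.xyz"
        path.write_text("hi")
        with pytest.raises(MeshFormatError):
            load_mesh(path)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "fmt,binary",
        [("ply", False), ("ply", True), ("obj", False)],
    )
    def test_mixed_mesh_round_trip(self, simple_quad_mesh, tmp_path, fmt, binary):
        path = tmp_path / f"m.{fmt}"
        save_mesh(simple_quad_mesh, path, binary=binary)
        back = load_mesh(path)
        assert back.n_faces == simple_quad_mesh.n_faces
        assert np.allclose(back.vertices, simple_quad_mesh.vertices, atol=1e-6)
        assert np.array_equal(back.faces, simple_quad_mesh.faces)

    @pytest.mark.parametrize("binary", [False, True])
    def test_stl_round_trip_triangulates_quads(
        self, simple_quad_mesh, tmp_path, binary
    ):
        path = tmp_path / "m.stl"
        save_mesh(simple_quad_mesh, path, binary=binary)
        back = load_mesh(path)
        assert back.is_triangle.all()
        assert back.n_faces == 3  # quad split into 2 triangles + 1 triangle
        rel = abs(back.face_areas().sum() / simple_quad_mesh.face_areas().sum() - 1)
        assert rel < 1e-9

    @pytest.mark.parametrize("binary", [False, True])
    def test_ply_face_field_round_trip(self, simple_quad_mesh, tmp_path, binary):
        field = np.array([12.375, -0.001953125])  # exactly representable
        path = tmp_path / "m.ply"
        save_mesh(
            simple_quad_mesh, path, scalar_fields={"stress": field}, binary=binary
        )
        back = load_mesh(path)
        assert np.array_equal(back.face_fields["stress"], field)

    def test_ply_irrational_field_round_trip(self, simple_quad_mesh, tmp_path):
        field = np.array([np.pi, np.sqrt(2.0)])
        path = tmp_path / "m.ply"
        save_mesh(simple_quad_mesh, path, scalar_fields={"stress": field})
        back = load_mesh(path)
        assert np.array_equal(back.face_fields["stress"], field)

    def test_trimesh_reads_our_exports(self, simple_quad_mesh, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        for name, binary in (("a.stl", True), ("b.ply", False)):
            path = tmp_path / name
            save_mesh(simple_quad_mesh, path, binary=binary)
            tm = trimesh.load_mesh(path, process=False)
            assert np.isclose(
                tm.area, simple_quad_mesh.face_areas().sum(), rtol=1e-6
            )

    def test_field_length_mismatch(self, simple_quad_mesh, tmp_path):
        with pytest.raises(DimensionError):
            save_mesh(
                simple_quad_mesh,
                tmp_path / "m.ply",
                scalar_fields={"s": np.arange(5.0)},
            )

    def test_stl_rejects_fields(self, simple_quad_mesh, tmp_path):
        with pytest.raises(ParameterError):
            save_mesh(
                simple_quad_mesh,
                tmp_path / "m.stl",
                scalar_fields={"s": np.zeros(2)},
            )

    def test_vtk_export_structure(self, simple_quad_mesh, tmp_path):
        path = tmp_path / "m.vtk"
        save_mesh(simple_quad_mesh, path, scalar_fields={"sigma1": np.ones(2)})
        text = path.read_text()
        assert "DATASET POLYDATA" in text
        assert "CELL_DATA 2" in text
        assert "SCALARS sigma1 double 1" in text


class TestValidation:
    def test_degenerate_face_rejected(self):
        with pytest.raises(MeshFormatError, match="degenerate"):
            SurfaceMesh(np.eye(3), np.array([[0, 1, 1, -1]]))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(MeshFormatError, match="out of range"):
            SurfaceMesh(np.eye(3), np.array([[0, 1, 7, -1]]))


class TestSmoothing:
    def test_flat_grid_fixed_point(self):
        mesh = grid_mesh()
        out = smooth_mesh(mesh, iterations=5, weight=0.8)
        # interior vertices are exact fixed points; boundary vertices may
        # shrink tangentially but never leave the plane
        interior = (
            (mesh.vertices[:, 0] > 0)
            & (mesh.vertices[:, 0] < 5)
            & (mesh.vertices[:, 2] > 0)
            & (mesh.vertices[:, 2] < 5)
        )
        assert np.abs(out.vertices[interior] - mesh.vertices[interior]).max() < 1e-9
        assert np.abs(out.vertices[:, 1]).max() < 1e-12

    def test_spike_moves_to_neighbor_mean(self):
        # spike an interior vertex 1 mm above a flat grid
        mesh = grid_mesh(spike=14)  # (2, 2) interior vertex of a 6x6 grid
        out = smooth_mesh(mesh, iterations=1, weight=1.0)
        assert abs(out.vertices[14, 1]) < 1e-9

    def test_zero_iterations_identity(self, simple_quad_mesh):
        out = smooth_mesh(simple_quad_mesh, iterations=0)
        assert np.array_equal(out.vertices, simple_quad_mesh.vertices)

    def test_connectivity_unchanged(self):
        mesh = grid_mesh(spike=14)
        out = smooth_mesh(mesh, iterations=3, weight=0.5)
        assert np.array_equal(out.faces, mesh.faces)

    def test_invalid_params(self, simple_quad_mesh):
        with pytest.raises(ParameterError):
            smooth_mesh(simple_quad_mesh, iterations=-1)
        with pytest.raises(ParameterError):
            smooth_mesh(simple_quad_mesh, iterations=1, weight=1.5)
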