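"""Surface-mesh container, file I/O and smoothing.

Meshes are occlusal surface shells in millimetres. Mixed triangle/quad
faces are kept in memory (quads are only triangulated where a format or
the contact solver requires it). Faces are stored as an ``(m, 4)`` int64
array where triangle rows carry ``-1`` in the last column.

Supported formats: STL (ASCII and binary, triangles only), PLY (ASCII and
binary little-endian, mixed faces, per-face scalar fields), OBJ (mixed
faces) and legacy-VTK polydata export with per-face scalar fields.
"""

from __future__ import annotations

import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tri import triangle_areas
from .errors import (
    DimensionError,
    EmptyMeshError,
    MeshFormatError,
    ParameterError,
)

__all__ = ["SurfaceMesh", "load_mesh", "save_mesh", "smooth_mesh"]


@dataclass
class SurfaceMesh:
    """Triangle/quad surface mesh in mm.

    Attributes
    ----------
    vertices : (n, 3) float64 array
    faces : (m, 4) int64 array, ``-1`` in column 3 marks a triangle
    face_fields : per-face scalar fields (e.g. stress maps) keyed by name
    provenance : free-text notes recording lossy conversions
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_fields: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        faces = np.asarray(self.faces, dtype=np.int64)
        if faces.ndim != 2 or faces.shape[1] not in (3, 4):
            raise DimensionError(
                f"faces must be (m, 3) or (m, 4), got {faces.shape}"
            )
        if faces.shape[1] == 3:
            faces = np.column_stack(
                [faces, np.full(len(faces), -1, dtype=np.int64)]
            )
        self.faces = np.ascontiguousarray(faces)
        self._version = 0
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError(
                f"vertices must be (n, 3), got {self.vertices.shape}"
            )
        if len(self.faces):
            if self.faces.max() >= len(self.vertices):
                raise MeshFormatError(
                    f"face index {int(self.faces.max())} out of range for "
                    f"{len(self.vertices)} vertices"
                )
            tri = self.is_triangle
            if self.faces[:, :3].min() < 0 or (
                np.any(~tri) and self.faces[~tri].min() < 0
            ):
                raise MeshFormatError("negative vertex index in face")
            for j, k in ((0, 1), (0, 2), (1, 2)):
                if np.any(self.faces[:, j] == self.faces[:, k]):
                    bad = int(
                        np.nonzero(self.faces[:, j] == self.faces[:, k])[0][0]
                    )
                    raise MeshFormatError(
                        f"degenerate face {bad}: repeated vertex"
                    )
            quad = self.faces[~tri]
            if len(quad):
                for j in range(3):
                    if np.any(quad[:, j] == quad[:, 3]):
                        raise MeshFormatError(
                            "degenerate quad face: repeated vertex"
                        )
        for name, values in self.face_fields.items():
            if len(values) != len(self.faces):
                raise DimensionError(
                    f"face field {name!r} has {len(values)} values for "
                    f"{len(self.faces)} faces"
                )

    # -- basic queries -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_triangle(self) -> np.ndarray:
        return self.faces[:, 3] < 0

    @property
    def version(self) -> int:
        """Mutation counter used to detect stale spatial indices."""
        return self._version

    def bump_version(self) -> None:
        """Mark the mesh as modified (invalidates spatial indices)."""
        self._version += 1

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: np.array(v) for k, v in self.face_fields.items()},
            list(self.provenance),
        )

    def face_centroids(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        tri = self.is_triangle
        out = np.empty((len(f), 3))
        out[tri] = v[f[tri, :3]].mean(axis=1)
        if np.any(~tri):
            out[~tri] = v[f[~tri][:, :4]].mean(axis=1)
        return out

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        tri = self.is_triangle
        out = np.empty(len(f))
        out[tri] = triangle_areas(v[f[tri, 0]], v[f[tri, 1]], v[f[tri, 2]])
        q = f[~tri]
        if len(q):
            out[~tri] = triangle_areas(
                v[q[:, 0]], v[q[:, 1]], v[q[:, 2]]
            ) + triangle_areas(v[q[:, 0]], v[q[:, 2]], v[q[:, 3]])
        return out

    def triangulated(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangulate quads by their shortest diagonal.

        Returns ``(tris, parent)`` where ``tris`` is ``(k, 3)`` and
        ``parent[i]`` is the index of the originating mixed face.
        """
        f = self.faces
        tri_mask = self.is_triangle
        tris = [f[tri_mask, :3]]
        parents = [np.nonzero(tri_mask)[0]]
        q_idx = np.nonzero(~tri_mask)[0]
        if len(q_idx):
            q = f[q_idx]
            v = self.vertices
            d02 = np.linalg.norm(v[q[:, 0]] - v[q[:, 2]], axis=1)
            d13 = np.linalg.norm(v[q[:, 1]] - v[q[:, 3]], axis=1)
            use02 = d02 <= d13
            t1 = np.where(
                use02[:, None], q[:, [0, 1, 2]], q[:, [0, 1, 3]]
            )
            t2 = np.where(
                use02[:, None], q[:, [0, 2, 3]], q[:, [1, 2, 3]]
            )
            tris += [t1, t2]
            parents += [q_idx, q_idx]
        return np.vstack(tris).astype(np.int64), np.concatenate(parents)


# ---------------------------------------------------------------------
# loading


def load_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Load an STL/PLY/OBJ mesh (units mm).

    ``fmt`` overrides the extension-based format guess. ASCII/binary
    variants are auto-detected. Per-face scalar fields found in PLY files
    are returned in ``mesh.face_fields``.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    data = path.read_bytes()
    if fmt == "stl":
        mesh = _load_stl(data, path)
    elif fmt == "ply":
        mesh = _load_ply(data, path)
    elif fmt == "obj":
        mesh = _load_obj(data, path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise EmptyMeshError(f"{path}: mesh has no geometry")
    return mesh


def _load_stl(data: bytes, path: Path) -> SurfaceMesh:
    # A binary STL is 84 + 50 * n_triangles bytes; use the size check
    # rather than the unreliable "solid" prefix.
    if len(data) >= 84:
        (n,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * n:
            return _load_stl_binary(data, n)
    if data[:5].lower() == b"solid":
        return _load_stl_ascii(data, path)
    raise MeshFormatError(
        f"{path}: not a valid STL (size {len(data)} bytes does not match a "
        "binary record count and byte 0 does not start an ASCII 'solid')"
    )


def _load_stl_binary(data: bytes, n: int) -> SurfaceMesh:
    rec = np.dtype(
        [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
    )
    body = np.frombuffer(data, dtype=rec, count=n, offset=84)
    verts = body["verts"].reshape(-1, 3).astype(np.float64)
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    mesh = SurfaceMesh(verts, faces)
    return _merge_duplicate_vertices(mesh)


def _load_stl_ascii(data: bytes, path: Path) -> SurfaceMesh:
    verts: list[list[float]] = []
    current: list[list[float]] = []
    tri_count = 0
    for lineno, raw in enumerate(data.decode("utf-8", "replace").splitlines(), 1):
        tokens = raw.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key == "vertex":
            if len(tokens) != 4:
                raise MeshFormatError(
                    f"{path}:{lineno}: vertex line needs 3 coordinates"
                )
            try:
                current.append([float(t) for t in tokens[1:4]])
            except ValueError:
                raise MeshFormatError(
                    f"{path}:{lineno}: non-numeric vertex coordinate"
                ) from None
        elif key == "endfacet":
            if len(current) != 3:
                raise MeshFormatError(
                    f"{path}:{lineno}: facet closed with "
                    f"{len(current)} vertices (need 3)"
                )
            verts.extend(current)
            current = []
            tri_count += 1
    if tri_count == 0:
        raise EmptyMeshError(f"{path}: ASCII STL contains no facets")
    v = np.array(verts)
    faces = np.arange(len(v), dtype=np.int64).reshape(-1, 3)
    return _merge_duplicate_vertices(SurfaceMesh(v, faces))


def _merge_duplicate_vertices(mesh: SurfaceMesh) -> SurfaceMesh:
    """Weld exactly-coincident vertices (STL stores them per-facet)."""
    uniq, inverse = np.unique(mesh.vertices, axis=0, return_inverse=True)
    faces = mesh.faces.copy()
    tri = mesh.is_triangle
    faces[:, :3] = inverse[faces[:, :3]]
    if np.any(~tri):
        faces[~tri, 3] = inverse[faces[~tri, 3]]
    return SurfaceMesh(uniq, faces, provenance=list(mesh.provenance))


_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _load_ply(data: bytes, path: Path) -> SurfaceMesh:
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise MeshFormatError(f"{path}: missing PLY header (byte offset 0)")
    header_end = data.find(b"\n", end) + 1
    header = data[:header_end].decode("ascii", "replace").splitlines()

    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, props)
    for lineno, line in enumerate(header, 1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise MeshFormatError(
                    f"{path}:{lineno}: property before any element"
                )
            if tokens[1] == "list":
                elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
            else:
                elements[-1][2].append(("scalar", tokens[1], tokens[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(
            f"{path}: unsupported PLY format {fmt!r} "
            "(ascii or binary_little_endian only)"
        )

    if fmt == "ascii":
        body_lines = (
            data[header_end:].decode("utf-8", "replace").splitlines()
        )
        return _parse_ply_elements_ascii(body_lines, elements, path)
    return _parse_ply_elements_binary(data, header_end, elements, path)


def _parse_ply_elements_ascii(lines, elements, path) -> SurfaceMesh:
    verts = None
    faces: list[list[int]] = []
    fields: dict[str, list] = {}
    cursor = 0
    rows = [ln.split() for ln in lines if ln.strip()]
    for name, count, props in elements:
        chunk = rows[cursor : cursor + count]
        if len(chunk) < count:
            raise MeshFormatError(
                f"{path}: element {name!r} truncated "
                f"({len(chunk)} of {count} rows)"
            )
        cursor += count
        if name == "vertex":
            cols = {p[2]: i for i, p in enumerate(props) if p[0] == "scalar"}
            try:
                idx = [cols["x"], cols["y"], cols["z"]]
            except KeyError:
                raise MeshFormatError(
                    f"{path}: vertex element lacks x/y/z properties"
                ) from None
            arr = np.array([[float(t) for t in r] for r in chunk])
            verts = arr[:, idx]
        elif name == "face":
            scalar_names = [p[2] for p in props if p[0] == "scalar"]
            for f in scalar_names:
                fields[f] = []
            for r in chunk:
                n = int(r[0])
                if n not in (3, 4):
                    raise MeshFormatError(
                        f"{path}: face with {n} vertices (3 or 4 supported)"
                    )
                faces.append([int(t) for t in r[1 : 1 + n]])
                for j, f in enumerate(scalar_names):
                    fields[f].append(float(r[1 + n + j]))
    return _assemble_ply(verts, faces, fields, path)


def _parse_ply_elements_binary(data, offset, elements, path) -> SurfaceMesh:
    verts = None
    faces: list[list[int]] = []
    fields: dict[str, list] = {}
    for name, count, props in elements:
        if name == "vertex" and all(p[0] == "scalar" for p in props):
            dtype = np.dtype(
                [(p[2], "<" + _PLY_DTYPES[p[1]]) for p in props]
            )
            arr = np.frombuffer(data, dtype=dtype, count=count, offset=offset)
            offset += dtype.itemsize * count
            verts = np.column_stack(
                [arr["x"], arr["y"], arr["z"]]
            ).astype(np.float64)
        elif name == "face":
            scalar_props = [p for p in props if p[0] == "scalar"]
            for p in scalar_props:
                fields[p[2]] = []
            list_prop = next(p for p in props if p[0] == "list")
            cnt_dt = np.dtype("<" + _PLY_DTYPES[list_prop[1]])
            idx_dt = np.dtype("<" + _PLY_DTYPES[list_prop[2]])
            for _ in range(count):
                n = int(
                    np.frombuffer(data, cnt_dt, count=1, offset=offset)[0]
                )
                offset += cnt_dt.itemsize
                if n not in (3, 4):
                    raise MeshFormatError(
                        f"{path}: face with {n} vertices at byte "
                        f"{offset - cnt_dt.itemsize}"
                    )
                faces.append(
                    list(np.frombuffer(data, idx_dt, count=n, offset=offset))
                )
                offset += idx_dt.itemsize * n
                for p in scalar_props:
                    dt = np.dtype("<" + _PLY_DTYPES[p[1]])
                    fields[p[2]].append(
                        float(np.frombuffer(data, dt, count=1, offset=offset)[0])
                    )
                    offset += dt.itemsize
        else:  # skip unknown fixed-size elements
            row = sum(
                np.dtype(_PLY_DTYPES[p[1]]).itemsize
                for p in props
                if p[0] == "scalar"
            )
            offset += row * count
    return _assemble_ply(verts, faces, fields, path)


def _assemble_ply(verts, faces, fields, path) -> SurfaceMesh:
    if verts is None:
        raise MeshFormatError(f"{path}: PLY has no vertex element")
    packed = np.full((len(faces), 4), -1, dtype=np.int64)
    for i, f in enumerate(faces):
        packed[i, : len(f)] = f
    mesh = SurfaceMesh(verts, packed)
    for k, v in fields.items():
        mesh.face_fields[k] = np.asarray(v, dtype=np.float64)
    mesh.validate()
    return mesh


def _load_obj(data: bytes, path: Path) -> SurfaceMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, line in enumerate(data.decode("utf-8", "replace").splitlines(), 1):
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        if tokens[0] == "v":
            if len(tokens) < 4:
                raise MeshFormatError(
                    f"{path}:{lineno}: vertex line needs 3 coordinates"
                )
            try:
                verts.append([float(t) for t in tokens[1:4]])
            except ValueError:
                raise MeshFormatError(
                    f"{path}:{lineno}: non-numeric vertex coordinate"
                ) from None
        elif tokens[0] == "f":
            idx = []
            for t in tokens[1:]:
                try:
                    i = int(t.split("/")[0])
                except ValueError:
                    raise MeshFormatError(
                        f"{path}:{lineno}: bad face index {t!r}"
                    ) from None
                idx.append(i - 1 if i > 0 else len(verts) + i)
            if len(idx) not in (3, 4):
                raise MeshFormatError(
                    f"{path}:{lineno}: face with {len(idx)} vertices "
                    "(3 or 4 supported)"
                )
            faces.append(idx)
    packed = np.full((len(faces), 4), -1, dtype=np.int64)
    for i, f in enumerate(faces):
        packed[i, : len(f)] = f
    return SurfaceMesh(np.array(verts).reshape(-1, 3), packed)


# ---------------------------------------------------------------------
# saving


def save_mesh(
    mesh: SurfaceMesh,
    path,
    fmt: str | None = None,
    scalar_fields: dict | None = None,
    binary: bool = False,
) -> None:
    """Write a mesh to STL/PLY/OBJ/VTK.

    PLY and VTK carry per-face scalar fields; STL and OBJ cannot and a
    non-empty ``scalar_fields`` raises. Saving quads to STL triangulates
    them (area-conserving split, noted in the file's provenance comment
    where the format allows comments).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    scalar_fields = dict(scalar_fields or {})
    for name, values in scalar_fields.items():
        if len(values) != mesh.n_faces:
            raise DimensionError(
                f"scalar field {name!r} has {len(values)} values for "
                f"{mesh.n_faces} faces"
            )
    if fmt == "stl":
        if scalar_fields:
            raise ParameterError("STL cannot carry per-face scalar fields")
        _save_stl(mesh, path, binary)
    elif fmt == "ply":
        _save_ply(mesh, path, scalar_fields, binary)
    elif fmt == "obj":
        if scalar_fields:
            raise ParameterError("OBJ cannot carry per-face scalar fields")
        _save_obj(mesh, path)
    elif fmt == "vtk":
        _save_vtk(mesh, path, scalar_fields)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")


def _save_stl(mesh: SurfaceMesh, path: Path, binary: bool) -> None:
    tris, _ = mesh.triangulated()
    v = mesh.vertices
    a, b, c = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(norms > 0, n / norms, 0.0)
    if binary:
        header = b"occlustress binary STL".ljust(80, b" ")
        rec = np.zeros(
            len(tris),
            dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
        rec["n"] = n
        rec["v"] = np.stack([a, b, c], axis=1)
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tris)))
            fh.write(rec.tobytes())
        return
    lines = ["solid occlustress"]
    for i in range(len(tris)):
        lines.append(f"  facet normal {n[i,0]:.9e} {n[i,1]:.9e} {n[i,2]:.9e}")
        lines.append("    outer loop")
        for p in (a[i], b[i], c[i]):
            lines.append(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid occlustress")
    path.write_text("\n".join(lines) + "\n")


def _save_ply(
    mesh: SurfaceMesh, path: Path, fields: dict, binary: bool
) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        "comment produced by occlustress",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
    ]
    for name in fields:
        header.append(f"property double {name}")
    header.append("end_header")
    tri = mesh.is_triangle
    counts = np.where(tri, 3, 4)
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(mesh.vertices.astype("<f8").tobytes())
            for i in range(mesh.n_faces):
                k = int(counts[i])
                fh.write(struct.pack("<B", k))
                fh.write(
                    mesh.faces[i, :k].astype("<i4").tobytes()
                )
                for name in fields:
                    fh.write(struct.pack("<d", float(fields[name][i])))
        return
    lines = list(header)
    for p in mesh.vertices:
        lines.append(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    for i in range(mesh.n_faces):
        k = int(counts[i])
        row = [str(k)] + [str(int(j)) for j in mesh.faces[i, :k]]
        row += [repr(float(fields[name][i])) for name in fields]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def _save_obj(mesh: SurfaceMesh, path: Path) -> None:
    lines = ["# produced by occlustress"]
    for p in mesh.vertices:
        lines.append(f"v {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    tri = mesh.is_triangle
    for i in range(mesh.n_faces):
        k = 3 if tri[i] else 4
        lines.append("f " + " ".join(str(int(j) + 1) for j in mesh.faces[i, :k]))
    path.write_text("\n".join(lines) + "\n")


def _save_vtk(mesh: SurfaceMesh, path: Path, fields: dict) -> None:
    tri = mesh.is_triangle
    counts = np.where(tri, 3, 4)
    lines = [
        "# vtk DataFile Version 3.0",
        "occlustress surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.vertices:
        lines.append(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    total = int(counts.sum()) + mesh.n_faces
    lines.append(f"POLYGONS {mesh.n_faces} {total}")
    for i in range(mesh.n_faces):
        k = int(counts[i])
        lines.append(
            f"{k} " + " ".join(str(int(j)) for j in mesh.faces[i, :k])
        )
    if fields:
        lines.append(f"CELL_DATA {mesh.n_faces}")
        for name, values in fields.items():
            safe = re.sub(r"\s+", "_", str(name))
            lines.append(f"SCALARS {safe} double 1")
            lines.append("LOOKUP_TABLE default")
            for v in values:
                lines.append(repr(float(v)))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# smoothing


def smooth_mesh(
    mesh: SurfaceMesh, iterations: int, weight: float = 1.0
) -> SurfaceMesh:
    """Iterative one-ring mean filter (umbrella Laplacian smoothing).

    Each pass moves every vertex toward the mean of its edge-connected
    neighbours by ``weight``; connectivity is unchanged. Vertices on the
    open boundary of the shell are pinned (so a flat patch is an exact
    fixed point and the surface rim does not shrink); isolated vertices
    are left in place with a warning. This is the mesh analogue of the
    mean filtering used to denoise scanned casts.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if not (0.0 < weight <= 1.0):
        raise ParameterError("weight must be in (0, 1]")
    out = mesh.copy()
    if iterations == 0:
        return out

    n = out.n_vertices
    edges, counts = _edge_list(out)
    if len(edges) == 0:
        return out
    boundary = np.zeros(n, dtype=bool)
    rim = edges[counts == 1]
    boundary[rim.ravel()] = True
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    deg = np.bincount(i, minlength=n).astype(float)
    isolated = deg == 0
    if np.any(isolated):
        warnings.warn(
            f"{int(isolated.sum())} isolated vertices left unsmoothed",
            stacklevel=2,
        )
    deg_safe = np.where(isolated, 1.0, deg)

    pinned = isolated | boundary
    v = out.vertices
    for _ in range(iterations):
        sums = np.zeros_like(v)
        np.add.at(sums, i, v[j])
        mean = sums / deg_safe[:, None]
        moved = v + weight * (mean - v)
        v = np.where(pinned[:, None], v, moved)
    out.vertices = np.ascontiguousarray(v)
    out.bump_version()
    return out


def _edge_list(mesh: SurfaceMesh):
    """Unique undirected edges and their incident-face counts."""
    f = mesh.faces
    tri = mesh.is_triangle
    pairs = []
    t = f[tri]
    if len(t):
        pairs += [t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]
    q = f[~tri]
    if len(q):
        pairs += [q[:, [0, 1]], q[:, [1, 2]], q[:, [2, 3]], q[:, [3, 0]]]
    if not pairs:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
    e = np.vstack(pairs)
    e.sort(axis=1)
    return np.unique(e, axis=0, return_counts=True)
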