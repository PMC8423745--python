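"""Closed-form contact benchmark scenes.

Small meshed configurations whose elastic-foundation contact solution
is known analytically, used to validate the penalty solver:

* rigid sphere (radius R) pressed depth delta into a foundation-backed
  plane: total normal force F = k * pi * R * delta**2 and pressure
  profile p(r) = k * (delta - r^2 / (2R));
* flat punch of area A at uniform penetration delta: p = k * delta
  everywhere, F = k * delta * A.
"""

from __future__ import annotations

import numpy as np

from .dentition import DentitionModel, MaterialParams, ToothLabelMap
from .mesh import SurfaceMesh

__all__ = [
    "meshed_plane",
    "spherical_cap",
    "flat_punch",
    "sphere_on_plane_model",
    "winkler_sphere_force",
]


def meshed_plane(
    half_extent: float = 3.0, step: float = 0.07, y: float = 0.0
) -> SurfaceMesh:
    """Quad-gridded plane at height ``y`` with outward normal -y."""
    n = 2 * int(np.ceil(half_extent / step)) + 1
    xs = np.linspace(-half_extent, half_extent, n)
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), np.full(X.size, y), Z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    quads = np.column_stack([a, b, c, d])
    v = verts
    nrm = np.cross(v[quads[:, 1]] - v[quads[:, 0]], v[quads[:, 3]] - v[quads[:, 0]])
    flip = nrm[:, 1] > 0  # want -y (facing the sphere below)
    quads[flip] = quads[flip][:, ::-1]
    return SurfaceMesh(verts, quads)


def spherical_cap(
    radius: float = 10.0,
    cap_extent: float = 2.6,
    step: float = 0.07,
) -> SurfaceMesh:
    """Upper cap of a sphere of ``radius``, apex at the origin (+y up).

    The cap is a triangulated height field over the apex neighbourhood:
    y(r) = -(R - sqrt(R^2 - r^2)), so the apex touches y = 0 from below.
    """
    n = 2 * int(np.ceil(cap_extent / step)) + 1
    xs = np.linspace(-cap_extent, cap_extent, n)
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    r2 = X**2 + Z**2
    Y = -(radius - np.sqrt(np.maximum(radius**2 - r2, 0.0)))
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.vstack(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    v = verts
    nrm = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    flip = nrm[:, 1] < 0  # outward normal +y at the apex
    tris[flip] = tris[flip][:, ::-1]
    return SurfaceMesh(verts, tris)


def flat_punch(
    side: float, step: float = 0.1, y: float = 0.0
) -> SurfaceMesh:
    """Square flat punch of edge ``side`` at height ``y`` (+y normals)."""
    n = max(2 * int(np.ceil(side / (2 * step))) + 1, 2)
    xs = np.linspace(-side / 2.0, side / 2.0, n)
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), np.full(X.size, y), Z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    quads = np.column_stack([a, b, c, d])
    v = verts
    nrm = np.cross(v[quads[:, 1]] - v[quads[:, 0]], v[quads[:, 3]] - v[quads[:, 0]])
    flip = nrm[:, 1] < 0
    quads[flip] = quads[flip][:, ::-1]
    return SurfaceMesh(verts, quads)


def sphere_on_plane_model(
    radius: float = 10.0,
    step: float = 0.07,
    cap_extent: float = 2.6,
    plane_extent: float = 3.0,
    material: MaterialParams | None = None,
) -> DentitionModel:
    """Sphere (moving lower) below a fixed plane at y = 0.

    Translating the lower body by +delta in y presses the apex depth
    delta past the plane.
    """
    upper = meshed_plane(plane_extent, step=step, y=0.0)
    lower = spherical_cap(radius, cap_extent, step=step)
    return DentitionModel(
        upper,
        lower,
        ToothLabelMap(np.zeros(upper.n_faces, dtype=np.int64)),
        ToothLabelMap(np.zeros(lower.n_faces, dtype=np.int64)),
        material or MaterialParams(),
    )


def winkler_sphere_force(k: float, radius: float, delta: float) -> float:
    """Closed-form foundation force for a rigid sphere: k pi R delta^2."""
    return k * np.pi * radius * delta**2
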