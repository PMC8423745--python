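"""Penalty-formulation contact between the moving lower and fixed upper arch.

The lower dentition is sampled at its face centroids (one material
point per face). Every frame the signed gap to the fixed upper surface
is re-established from the current positions (finite sliding: no
persistent anchor points); interpenetration is penalised by an elastic
foundation (Winkler) layer of stiffness

    k = E* / h,   E* = E / (1 - nu^2)

with E converted to MPa and the foundation thickness h in mm, giving k
in N/mm^3. Contact pressure is p = k * penetration; sliding friction is
rigid Coulomb (tau = mu * p opposing the slip direction, no elastic
slip, zero traction at zero slip); the reported maximum principal
contact stress is the Mohr's-circle major value of the (p, tau) pair,

    sigma1 = p/2 + sqrt((p/2)^2 + tau^2),

a positive magnitude per lower face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._tri import closest_point_on_triangles, triangle_normals
from .dentition import MaterialParams
from .errors import EmptyMeshError, ParameterError, StaleIndexError
from .mesh import SurfaceMesh

__all__ = [
    "SpatialIndex",
    "build_spatial_index",
    "signed_gap",
    "foundation_stiffness",
    "penalty_pressure",
    "friction_traction",
    "max_principal_stress",
    "resolve_frame",
    "ContactState",
    "DEFAULT_CUTOFF_MM",
]

DEFAULT_CUTOFF_MM = 5.0


class SpatialIndex:
    """Nearest-triangle index over a (triangulated) surface mesh.

    Exactness contract: queries return the same face and distance as an
    exhaustive search over all triangles (ties broken by the lowest
    original face index). Candidate pruning uses a centroid KD-tree
    with triangle-circumradius bounds, so the pruning is conservative.
    """

    def __init__(self, mesh: SurfaceMesh) -> None:
        if mesh.n_faces == 0 or mesh.n_vertices == 0:
            raise EmptyMeshError("cannot index an empty mesh")
        self._mesh = mesh
        self._mesh_version = mesh.version
        tris, parents = mesh.triangulated()
        v = mesh.vertices
        self.tri_a = v[tris[:, 0]]
        self.tri_b = v[tris[:, 1]]
        self.tri_c = v[tris[:, 2]]
        self.parent_face = parents
        self.normals = triangle_normals(self.tri_a, self.tri_b, self.tri_c)
        self.centroids = (self.tri_a + self.tri_b + self.tri_c) / 3.0
        self.radii = np.maximum.reduce(
            [
                np.linalg.norm(self.tri_a - self.centroids, axis=1),
                np.linalg.norm(self.tri_b - self.centroids, axis=1),
                np.linalg.norm(self.tri_c - self.centroids, axis=1),
            ]
        )
        self.max_radius = float(self.radii.max())
        self.tree = cKDTree(self.centroids)

    @property
    def n_triangles(self) -> int:
        return len(self.tri_a)

    def _check_fresh(self) -> None:
        if self._mesh.version != self._mesh_version:
            raise StaleIndexError(
                "source mesh changed since the index was built; rebuild "
                "with build_spatial_index"
            )

    def query(
        self, points: np.ndarray, cutoff: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Nearest triangle per query point.

        Returns ``(distance, face_id, closest_point, normal)``. Points
        farther than ``cutoff`` from every triangle get ``inf`` distance
        and face id ``-1`` ("far" sentinel).
        """
        self._check_fresh()
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        dist = np.full(n, np.inf)
        face = np.full(n, -1, dtype=np.int64)
        cp = np.zeros((n, 3))
        nrm = np.zeros((n, 3))

        d0, _ = self.tree.query(pts)
        active = np.arange(n)
        if cutoff is not None:
            # conservative lower bound on the true distance
            active = active[d0 - self.max_radius <= cutoff]
            if len(active) == 0:
                return dist, face, cp, nrm
        radius = d0[active] + 2.0 * self.max_radius + 1e-12
        groups = self.tree.query_ball_point(pts[active], radius)

        qi = np.concatenate(
            [np.full(len(g), i) for i, g in zip(active, groups)]
        ).astype(np.int64)
        ti = np.concatenate([np.asarray(g, dtype=np.int64) for g in groups])
        closest = closest_point_on_triangles(
            pts[qi], self.tri_a[ti], self.tri_b[ti], self.tri_c[ti]
        )
        d = np.linalg.norm(pts[qi] - closest, axis=1)
        parents = self.parent_face[ti]
        order = np.lexsort((parents, d, qi))
        qi_s = qi[order]
        first = np.ones(len(order), dtype=bool)
        first[1:] = qi_s[1:] != qi_s[:-1]
        sel = order[first]
        rows = qi[sel]
        dist[rows] = d[sel]
        face[rows] = parents[sel]
        cp[rows] = closest[sel]
        nrm[rows] = self.normals[ti[sel]]
        if cutoff is not None:
            far = dist > cutoff
            dist[far] = np.inf
            face[far] = -1
            cp[far] = 0.0
            nrm[far] = 0.0
        return dist, face, cp, nrm


def build_spatial_index(mesh: SurfaceMesh) -> SpatialIndex:
    """Build a nearest-triangle index over the (fixed) upper mesh."""
    return SpatialIndex(mesh)


def signed_gap(
    points: np.ndarray,
    index: SpatialIndex,
    cutoff: float | None = DEFAULT_CUTOFF_MM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed distance of points to the indexed surface.

    Positive on the outward-normal side of the nearest face (open gap),
    negative when the point has passed through the surface
    (penetration). The pairing is re-established fresh at every call
    (finite sliding). Points beyond ``cutoff`` return ``+inf`` and face
    id ``-1``.

    Returns ``(signed_distance, face_id, contact_normal)``.
    """
    dist, face, cp, nrm = index.query(points, cutoff=cutoff)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    side = np.einsum("ij,ij->i", pts - cp, nrm)
    signed = np.where(np.isfinite(dist), np.where(side >= 0, dist, -dist), np.inf)
    return signed, face, nrm


def foundation_stiffness(
    material: MaterialParams, unit_scale: float = 1000.0
) -> float:
    """Elastic-foundation penalty stiffness k = E*/h in N/mm^3.

    ``unit_scale`` converts the stored elastic modulus (GPa) to MPa.
    Defaults (E=84 GPa, nu=0.3, h=2 mm) give k ~= 46 154 N/mm^3.
    """
    if material.foundation_thickness <= 0:
        raise ParameterError("foundation_thickness must be > 0")
    e_star = (material.elastic_modulus * unit_scale) / (
        1.0 - material.poisson_ratio**2
    )
    return e_star / material.foundation_thickness


def penalty_pressure(g_signed, k: float):
    """Penalty contact pressure p = k * max(-g_signed, 0) in MPa."""
    if k <= 0:
        raise ParameterError("penalty stiffness k must be > 0")
    g = np.asarray(g_signed, dtype=np.float64)
    pen = np.where(np.isfinite(g), np.maximum(-g, 0.0), 0.0)
    return k * pen


def friction_traction(
    p, slip_velocity, mu: float, speed_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid-Coulomb sliding traction.

    tau = mu * p opposing the slip direction where the tangential slip
    speed is positive; zero traction at zero slip (no elastic slip, no
    stick-force recovery in a kinematically driven model).

    Returns ``(tau_magnitude, direction)`` with zero direction rows
    where there is no sliding.
    """
    if mu < 0:
        raise ParameterError("friction coefficient must be >= 0")
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    v = np.atleast_2d(np.asarray(slip_velocity, dtype=np.float64))
    speed = np.linalg.norm(v, axis=1)
    sliding = speed > speed_tol
    tau = np.where(sliding, mu * p, 0.0)
    direction = np.zeros_like(v)
    direction[sliding] = -v[sliding] / speed[sliding, None]
    return tau, direction


def max_principal_stress(p, tau):
    """Mohr's-circle major principal value of the (p, tau) traction pair."""
    p = np.asarray(p, dtype=np.float64)
    tau = np.asarray(tau, dtype=np.float64)
    return p / 2.0 + np.sqrt((p / 2.0) ** 2 + tau**2)


@dataclass
class ContactState:
    """Per-lower-face contact solution at one trajectory frame."""

    frame_index: int
    points: np.ndarray  # transformed lower-face centroids (n, 3)
    signed_gap: np.ndarray  # (n,) mm, +inf = far
    penetration: np.ndarray  # (n,) mm, >= 0
    pressure: np.ndarray  # (n,) MPa
    shear: np.ndarray  # (n,) MPa
    slip_direction: np.ndarray  # (n, 3) unit vectors or zero rows
    sigma1: np.ndarray  # (n,) MPa
    face_area: np.ndarray  # (n,) mm^2
    nearest_face: np.ndarray  # (n,) upper face id or -1

    @property
    def contact(self) -> np.ndarray:
        return self.pressure > 0.0

    @property
    def contact_area(self) -> float:
        return float(self.face_area[self.contact].sum())

    @property
    def total_normal_force(self) -> float:
        return float((self.pressure * self.face_area).sum())


def resolve_frame(
    model,
    transform,
    index: SpatialIndex,
    prev_frame: ContactState | None = None,
    dt: float = 1.0,
    k: float | None = None,
    cutoff: float | None = DEFAULT_CUTOFF_MM,
    frame_index: int = 0,
) -> ContactState:
    """Quasi-static contact resolution for one trajectory frame.

    Transforms the lower-face centroids, computes signed gaps against
    the fixed upper index, penalty pressures, slip velocities (backward
    difference against ``prev_frame``; zero for the first frame),
    Coulomb shear and the per-face maximum principal contact stress.
    A frame with no near contacts is a valid empty state.
    """
    lower = model.lower
    centroids = transform.apply(lower.face_centroids())
    areas = lower.face_areas()
    mat = model.material
    if k is None:
        k = foundation_stiffness(mat)

    g, face, nrm = signed_gap(centroids, index, cutoff=cutoff)
    p = penalty_pressure(g, k)

    if prev_frame is None:
        vel = np.zeros_like(centroids)
    else:
        vel = (centroids - prev_frame.points) / dt
    # tangential slip: remove the normal component where in contact
    vn = np.einsum("ij,ij->i", vel, nrm)
    v_t = vel - vn[:, None] * nrm
    v_t[p <= 0.0] = 0.0
    tau, slip_dir = friction_traction(p, v_t, mat.friction_coefficient)
    sigma1 = max_principal_stress(p, tau)
    pen = np.where(np.isfinite(g), np.maximum(-g, 0.0), 0.0)
    return ContactState(
        frame_index=frame_index,
        points=centroids,
        signed_gap=g,
        penetration=pen,
        pressure=p,
        shear=tau,
        slip_direction=slip_dir,
        sigma1=sigma1,
        face_area=areas,
        nearest_face=face,
    )
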