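"""Parametric synthetic dentition generator.

Stands in for scanned dental casts: produces an upper (fixed) and lower
(moving) occlusal surface pair in centric relation with labelled teeth.

The lower arch is a band strip swept along an elliptic arch curve with
one cosine-profile cusp per tooth; every cusp tip lies on the occlusal
plane y = 0. The upper arch is a continuous "guidance funnel" canopy:
over each lower cusp it carries a small flat ceiling disc at that
tooth's centric clearance, and away from the fossae it descends at a
constant guidance slope with horizontal distance to the nearest fossa.
This idealisation extends natural cusp-incline guidance over the whole
excursion range, so that gliding tooth contact — which the recording
protocol demands — remains possible at the recorded movement amplitudes.

Per-tooth centric clearances emulate a posterior-guided occlusal scheme
(premolars in tightest centric contact, incisors relieved); an optional
interference bump on one tooth plants a balancing-side interference
like the one the recorded subject exhibited.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dentition import (
    ArchSpec,
    DentitionModel,
    ModificationSpec,
    ToothLabelMap,
)
from .errors import GenerationError, ParameterError
from .mesh import SurfaceMesh

__all__ = [
    "ArchParameters",
    "generate_synthetic_dentition",
    "interference_modification",
]

# tooth-position naming within a quadrant (FDI position digit 1..8)
_POSITION_NAMES = ("I1", "I2", "C", "P1", "P2", "M1", "M2", "M3")


@dataclass
class ArchParameters:
    """Geometry of the synthetic dentition.

    All lengths mm. Defaults emulate an adult arch whose occlusion
    admits gliding contact along the recorded jaw-movement envelope;
    ``clearances`` are per-tooth centric-gap offsets added to
    ``centric_gap`` (position order I1..M3). ``interference`` plants an
    extra-height bump on one tooth: (fdi, extra_height_mm).
    """

    teeth_per_quadrant: int = 7
    arch_half_width: float = 27.0
    arch_depth: float = 50.0
    tooth_widths: tuple = (5.5, 6.0, 7.0, 7.0, 7.0, 11.0, 10.5, 10.0)
    cusp_height: float = 2.5
    cusp_radius: float = 2.5
    cusp_flat_radius: float = 0.8
    centric_gap: float = 0.4
    clearances: tuple = (0.5, 0.5, 0.1, 0.0, 0.0, 0.25, 0.2, 0.2)
    band_width: float = 8.0
    lower_step: float = 0.7
    canopy_step: float = 1.0
    canopy_margin: float = 12.0
    funnel_slope: float = 0.42
    buccal_slope: float = 0.47
    ceiling_disc_radius: float = 1.5
    interference: tuple | None = None  # (fdi, extra_height)
    interference_radius: float = 2.0
    jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.teeth_per_quadrant <= 8):
            raise ParameterError("teeth_per_quadrant must be in 1..8")
        if self.centric_gap < 0:
            raise ParameterError("centric_gap must be >= 0")
        if min(self.clearances[: self.teeth_per_quadrant]) < 0:
            raise ParameterError("clearances must be >= 0")
        if self.cusp_height <= 0 or self.cusp_radius <= 0:
            raise ParameterError("cusp dimensions must be > 0")

    # -- arch curve ----------------------------------------------------
    def curve_table(self, n: int = 4000) -> tuple[np.ndarray, np.ndarray]:
        """Dense (arc length, point) table of the right-half arch curve."""
        arc, phi = self._arc_phi_table(n)
        a, b = self.arch_half_width, self.arch_depth
        pts = np.column_stack(
            [a * np.sin(phi), np.zeros(n), b * (np.cos(phi) - 1.0)]
        )
        return arc, pts

    def _arc_phi_table(self, n: int = 4000):
        a, b = self.arch_half_width, self.arch_depth
        phi = np.linspace(0.0, 0.55 * np.pi, n)
        seg = np.hypot(a * np.diff(np.sin(phi)), b * np.diff(np.cos(phi)))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return arc, phi

    def curve_frame(self, s):
        """Exact point, tangent and outward normal at arc length(s) s.

        The tangent at the midline (s = 0) is exactly +x, so the
        outward normal is exactly +z: the generated midline column is
        its own mirror image, which the mirror-symmetry invariant of
        symmetric arches relies on.
        """
        arc, phi_g = self._arc_phi_table()
        a, b = self.arch_half_width, self.arch_depth
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        phi = np.interp(s, arc, phi_g)
        p = np.column_stack(
            [a * np.sin(phi), np.zeros(len(s)), b * (np.cos(phi) - 1.0)]
        )
        t = np.column_stack(
            [a * np.cos(phi), np.zeros(len(s)), -b * np.sin(phi)]
        )
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        nrm = np.column_stack([-t[:, 2], np.zeros(len(s)), t[:, 0]])
        return p, t, nrm

    def tooth_spans(self) -> dict:
        """position (1-based) -> (s_mesial, s_distal) along the arch."""
        out = {}
        s = 0.0
        for k in range(self.teeth_per_quadrant):
            w = self.tooth_widths[k]
            out[k + 1] = (s, s + w)
            s += w
        return out

    def arch_spec(self, quadrants=(4, 3)) -> ArchSpec:
        arc, pts = self.curve_table()
        return ArchSpec(pts, arc, self.tooth_spans(), quadrants)

    def gap_of(self, position: int) -> float:
        return self.centric_gap + self.clearances[position - 1]


def generate_synthetic_dentition(
    params: ArchParameters | None = None, seed: int = 0
) -> DentitionModel:
    """Build a labelled upper+lower dentition in centric relation.

    Deterministic for a fixed seed (the seed only matters when
    ``jitter_mm > 0``; jitter is applied symmetrically so that mirror
    symmetry of symmetric parameters is preserved exactly).
    """
    p = params or ArchParameters()
    rng = np.random.default_rng(seed)

    arc, curve = p.curve_table()
    spans = p.tooth_spans()
    total_arc = spans[p.teeth_per_quadrant][1]
    if total_arc > arc[-1]:
        k = p.teeth_per_quadrant
        raise GenerationError(
            f"teeth {_fdi(4, k - 1)} and {_fdi(4, k)} overlap the arch end: "
            f"needed {total_arc:.1f} mm of {arc[-1]:.1f} mm available"
        )
    centers = {k: 0.5 * (a + b) for k, (a, b) in spans.items()}
    for k in range(1, p.teeth_per_quadrant):
        if centers[k + 1] - centers[k] < 2.0 * p.cusp_radius:
            raise GenerationError(
                f"cusps of teeth {_fdi(4, k)} and {_fdi(4, k + 1)} overlap: "
                f"spacing {centers[k + 1] - centers[k]:.2f} mm < "
                f"2 x cusp_radius {2 * p.cusp_radius:.2f} mm"
            )

    lower, lower_labels, fossae = _build_lower(p, arc, curve, spans, rng)
    upper, upper_labels = _build_upper(p, arc, curve, spans, fossae, rng)

    meta = {
        "arch_parameters": _params_dict(p),
        "seed": int(seed),
        "fossae": {int(f): [float(v) for v in xyz] for f, xyz in fossae.items()},
    }
    if p.interference is not None:
        fdi, extra = p.interference
        apex = list(fossae[int(fdi)])
        apex[1] = float(extra)
        meta["interference"] = {
            "fdi": int(fdi),
            "extra_height": float(extra),
            "radius": float(p.interference_radius),
            "apex": [float(v) for v in apex],
        }
    return DentitionModel(upper, lower, upper_labels, lower_labels, meta=meta)


def interference_modification(model: DentitionModel) -> ModificationSpec:
    """Carve spec that removes the generator's planted interference bump."""
    info = model.meta.get("interference")
    if not info:
        raise ParameterError("model has no planted interference")
    return ModificationSpec(
        target_label=info["fdi"],
        center=np.asarray(info["apex"], dtype=np.float64),
        radius=1.5 * info["radius"],
        removal_depth=info["extra_height"],
        removal_direction=np.array([0.0, 1.0, 0.0]),
    )


# ---------------------------------------------------------------------


def _fdi(quadrant: int, position: int) -> int:
    return 10 * quadrant + position


def _capped_cosine(rho, height, r_flat, r_out):
    """Height profile: flat plateau to ``r_flat``, cosine taper to 0 at
    ``r_out`` (a worn-cusp shape whose tip survives centroid sampling)."""
    taper = 0.5 * (1.0 + np.cos(np.pi * (rho - r_flat) / max(r_out - r_flat, 1e-9)))
    return height * np.where(rho <= r_flat, 1.0, np.where(rho < r_out, taper, 0.0))


def _params_dict(p: ArchParameters) -> dict:
    d = asdict(p)
    d["tooth_widths"] = list(d["tooth_widths"])
    d["clearances"] = list(d["clearances"])
    if d["interference"] is not None:
        d["interference"] = [int(d["interference"][0]), float(d["interference"][1])]
    return d


def _tooth_s_grid(p: ArchParameters, spans) -> np.ndarray:
    """Right-half arc samples; every tooth centre is hit exactly."""
    cols = [0.0]
    for k in sorted(spans):
        m, d = spans[k]
        n = 2 * int(np.ceil((d - m) / (2.0 * p.lower_step))) + 1
        sk = np.linspace(m, d, max(n, 3))
        cols.extend(sk[1:])
    return np.asarray(cols)


def _build_lower(p, arc, curve, spans, rng):
    s_right = _tooth_s_grid(p, spans)
    n_w = 2 * int(np.ceil(p.band_width / (2.0 * p.lower_step))) + 1
    w = np.linspace(-p.band_width / 2.0, p.band_width / 2.0, n_w)

    centers = {k: 0.5 * (a + b) for k, (a, b) in spans.items()}
    base = -p.cusp_height

    # height field on the (s, w) chart, right half
    S, W = np.meshgrid(s_right, w, indexing="ij")
    y = np.full_like(S, base)
    for k, sk in centers.items():
        rho = np.hypot(S - sk, W)
        y = np.maximum(
            y, base + _capped_cosine(rho, p.cusp_height, p.cusp_flat_radius, p.cusp_radius)
        )
    if p.jitter_mm > 0.0:
        y = y + rng.normal(0.0, p.jitter_mm, size=y.shape)

    pos, _, nrm = p.curve_frame(s_right)
    verts_right = (
        pos[:, None, :]
        + W[:, :, None] * nrm[:, None, :]
        + y[:, :, None] * np.array([0.0, 1.0, 0.0])[None, None, :]
    )

    fossae = {}
    for k, sk in centers.items():
        pt = p.curve_frame(sk)[0][0]
        fossae[_fdi(4, k)] = np.array([pt[0], 0.0, pt[2]])
        fossae[_fdi(3, k)] = np.array([-pt[0], 0.0, pt[2]])

    # mirror the symmetric arch: left half shares the s=0 column
    mirror = verts_right[1:][::-1].copy()
    mirror[:, :, 0] *= -1.0
    grid = np.concatenate([mirror, verts_right], axis=0)
    s_signed = np.concatenate([-s_right[1:][::-1], s_right])

    # interference bump on one tooth (applied after mirroring so it
    # breaks the left-right symmetry as a true unilateral interference)
    if p.interference is not None:
        fdi, extra = p.interference
        fdi = int(fdi)
        if fdi not in fossae:
            raise ParameterError(
                f"interference tooth {fdi} not in the generated arch"
            )
        sk = centers[fdi % 10] * (1.0 if fdi // 10 == 4 else -1.0)
        S_full, W_full = np.meshgrid(s_signed, w, indexing="ij")
        rho = np.hypot(S_full - sk, W_full)
        grid[:, :, 1] += _capped_cosine(
            rho, extra, p.cusp_flat_radius, p.interference_radius
        )

    mesh, face_cols = _grid_to_mesh(grid, upward=True)
    labels = _label_band_faces(p, spans, s_signed, face_cols, grid, mesh)
    return mesh, labels, fossae


def _build_upper(p, arc, curve, spans, fossae, rng):
    half_w = p.arch_half_width + p.canopy_margin
    nx = 2 * int(np.ceil(half_w / p.canopy_step)) + 1
    x = np.linspace(-half_w, half_w, nx)
    z_hi = p.canopy_margin * 0.7
    z_lo = -(p.arch_depth + p.canopy_margin)
    nz = int(np.ceil((z_hi - z_lo) / p.canopy_step)) + 1
    z = np.linspace(z_lo, z_hi, nz)

    X, Z = np.meshgrid(x, z, indexing="ij")
    H = np.full_like(X, -np.inf)
    codes = sorted(fossae)
    fx = np.array([fossae[c][0] for c in codes])
    fz = np.array([fossae[c][2] for c in codes])
    gaps = np.array([p.gap_of(c % 10) for c in codes])
    # outward (buccal) horizontal direction at each fossa, from the
    # gradient of the arch ellipse; guidance is slightly steeper on the
    # buccal than on the lingual/medial side of each tooth
    a2, b2 = p.arch_half_width**2, p.arch_depth**2
    nx_f = fx / a2
    nz_f = (fz + p.arch_depth) / b2
    nn = np.hypot(nx_f, nz_f)
    nx_f, nz_f = nx_f / nn, nz_f / nn
    for i in range(len(codes)):
        dx = X - fx[i]
        dz = Z - fz[i]
        rho = np.hypot(dx, dz)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosb = np.where(
                rho > 0.0, (dx * nx_f[i] + dz * nz_f[i]) / rho, 0.0
            )
        slope = p.funnel_slope + (p.buccal_slope - p.funnel_slope) * np.clip(
            cosb, 0.0, 1.0
        )
        Hk = gaps[i] - slope * np.maximum(0.0, rho - p.ceiling_disc_radius)
        H = np.maximum(H, Hk)
    if p.jitter_mm > 0.0:
        # symmetric jitter: draw on the right half and mirror in |x|
        half = rng.normal(0.0, p.jitter_mm, size=((nx + 1) // 2, nz))
        full = np.concatenate([half[1:][::-1], half], axis=0)
        H = H + full

    grid = np.stack([X, H, Z], axis=-1)
    mesh, face_idx = _grid_to_mesh(grid, upward=False)

    # labels: nearest fossa within half the tooth width (else 0)
    cent = mesh.face_centroids()
    d = np.hypot(
        cent[:, 0:1] - fx[None, :], cent[:, 2:3] - fz[None, :]
    )
    nearest = np.argmin(d, axis=1)
    labels = np.zeros(mesh.n_faces, dtype=np.int64)
    for i, c in enumerate(codes):
        widths = p.tooth_widths[c % 10 - 1]
        sel = (nearest == i) & (d[np.arange(len(cent)), nearest] <= widths / 2.0)
        # upper arch quadrants: 1 above lower-right (4), 2 above lower-left (3)
        q = 1 if c // 10 == 4 else 2
        labels[sel] = 10 * q + c % 10
    return mesh, ToothLabelMap(labels)


def _grid_to_mesh(grid: np.ndarray, upward: bool):
    """Quad mesh from an (ni, nj, 3) vertex grid; normals forced +/-y.

    Returns the mesh and, per face, the i-index of its lower-left grid
    cell (used for labelling band faces by arc interval).
    """
    ni, nj, _ = grid.shape
    verts = grid.reshape(-1, 3)
    idx = np.arange(ni * nj).reshape(ni, nj)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    quads = np.column_stack([a, b, c, d])

    # orient all faces with the requested vertical normal direction
    v = verts
    n = np.cross(v[quads[:, 1]] - v[quads[:, 0]], v[quads[:, 3]] - v[quads[:, 0]])
    flip = (n[:, 1] < 0.0) if upward else (n[:, 1] > 0.0)
    quads[flip] = quads[flip][:, ::-1]

    mesh = SurfaceMesh(verts, quads)
    face_i = np.repeat(np.arange(ni - 1), nj - 1)
    return mesh, face_i


def _label_band_faces(p, spans, s_signed, face_cols, grid, mesh):
    s_mid = 0.5 * (s_signed[:-1] + s_signed[1:])
    s_face = s_mid[face_cols]
    labels = np.zeros(mesh.n_faces, dtype=np.int64)
    for k, (m, d) in spans.items():
        right = (s_face > m) & (s_face < d)
        left = (s_face < -m) & (s_face > -d)
        labels[right] = _fdi(4, k)
        labels[left] = _fdi(3, k)
    return ToothLabelMap(labels)
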