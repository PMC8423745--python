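"""Dentition model types, tooth labelling and virtual occlusal carving.

Tooth identity uses FDI two-digit codes: quadrant (1 upper-right, 2
upper-left, 3 lower-left, 4 lower-right) then position 1 (central
incisor) to 8 (third molar). Label 0 marks unassigned faces.

Coordinate frame (shared by both arches): x = subject's right, y =
superior, z = anterior; origin at the mandibular incisal midpoint in
centric occlusion (the jaw-tracking magnet site). All lengths in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import LabelError, ParameterError
from .mesh import SurfaceMesh, load_mesh, save_mesh

__all__ = [
    "VALID_FDI",
    "MaterialParams",
    "ToothLabelMap",
    "DentitionModel",
    "ModificationSpec",
    "ArchSpec",
    "mirror_fdi",
    "assign_tooth_labels",
    "carve_region",
]

VALID_FDI = frozenset(
    10 * q + i for q in (1, 2, 3, 4) for i in range(1, 9)
)


def mirror_fdi(code: int) -> int:
    """Swap left/right quadrants (11<->21, 47<->37, ...); 0 stays 0."""
    if code == 0:
        return 0
    swap = {1: 2, 2: 1, 3: 4, 4: 3}
    return 10 * swap[code // 10] + code % 10


@dataclass(frozen=True)
class MaterialParams:
    """Enamel-shell material and contact parameters.

    elastic_modulus : GPa, default 84 (enamel)
    poisson_ratio : dimensionless, default 0.3
    friction_coefficient : Coulomb mu, default 0.1
    foundation_thickness : mm, elastic-foundation layer thickness used to
        convert (E, nu) into a penalty stiffness; default 2.
    """

    elastic_modulus: float = 84.0
    poisson_ratio: float = 0.3
    friction_coefficient: float = 0.1
    foundation_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ParameterError("elastic_modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ParameterError("poisson_ratio must be in [0, 0.5)")
        if self.friction_coefficient < 0:
            raise ParameterError("friction_coefficient must be >= 0")
        if self.foundation_thickness <= 0:
            raise ParameterError("foundation_thickness must be > 0")


class ToothLabelMap:
    """Per-face FDI labels for one arch (0 = unassigned)."""

    def __init__(self, labels) -> None:
        arr = np.asarray(labels, dtype=np.int64)
        bad = set(np.unique(arr)) - VALID_FDI - {0}
        if bad:
            raise LabelError(f"invalid FDI codes: {sorted(bad)}")
        self.labels = arr

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, ToothLabelMap) and np.array_equal(
            self.labels, other.labels
        )

    def teeth(self) -> list[int]:
        """Sorted FDI codes present (excluding 0)."""
        return sorted(set(np.unique(self.labels)) - {0})

    def faces_of(self, code: int) -> np.ndarray:
        return np.nonzero(self.labels == code)[0]

    def mirrored(self) -> "ToothLabelMap":
        out = np.array([mirror_fdi(c) for c in self.labels], dtype=np.int64)
        return ToothLabelMap(out)


@dataclass
class ModificationSpec:
    """Spherical carve region on one labelled tooth.

    Vertices of the target tooth inside the sphere move along
    ``-removal_direction`` with a cosine taper: the full
    ``removal_depth`` at the centre falling to zero at the boundary.
    """

    target_label: int
    center: np.ndarray
    radius: float
    removal_depth: float
    removal_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0])
    )

    def __post_init__(self) -> None:
        if self.target_label not in VALID_FDI:
            raise LabelError(f"invalid FDI code {self.target_label}")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")
        if self.removal_depth < 0:
            raise ParameterError("removal_depth must be >= 0")
        self.center = np.asarray(self.center, dtype=np.float64)
        d = np.asarray(self.removal_direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ParameterError("removal_direction must be non-zero")
        self.removal_direction = d / n


@dataclass
class DentitionModel:
    """Fixed upper arch + moving lower arch with labels and material."""

    upper: SurfaceMesh
    lower: SurfaceMesh
    upper_labels: ToothLabelMap
    lower_labels: ToothLabelMap
    material: MaterialParams = field(default_factory=MaterialParams)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.upper_labels) != self.upper.n_faces:
            raise LabelError("upper label count != upper face count")
        if len(self.lower_labels) != self.lower.n_faces:
            raise LabelError("lower label count != lower face count")

    def copy(self) -> "DentitionModel":
        return DentitionModel(
            self.upper.copy(),
            self.lower.copy(),
            ToothLabelMap(self.upper_labels.labels.copy()),
            ToothLabelMap(self.lower_labels.labels.copy()),
            self.material,
            dict(self.meta),
        )

    # -- persistence (a model directory of PLY + YAML) -----------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_mesh(
            self.upper,
            directory / "upper.ply",
            scalar_fields={"tooth": self.upper_labels.labels.astype(float)},
        )
        save_mesh(
            self.lower,
            directory / "lower.ply",
            scalar_fields={"tooth": self.lower_labels.labels.astype(float)},
        )
        info = {
            "material": {
                "E_gpa": self.material.elastic_modulus,
                "nu": self.material.poisson_ratio,
                "mu": self.material.friction_coefficient,
                "h_mm": self.material.foundation_thickness,
            },
            "meta": self.meta,
        }
        (directory / "model.yml").write_text(yaml.safe_dump(info))

    @classmethod
    def load(cls, directory) -> "DentitionModel":
        directory = Path(directory)
        upper = load_mesh(directory / "upper.ply")
        lower = load_mesh(directory / "lower.ply")
        info = yaml.safe_load((directory / "model.yml").read_text())
        m = info.get("material", {})
        material = MaterialParams(
            elastic_modulus=m.get("E_gpa", 84.0),
            poisson_ratio=m.get("nu", 0.3),
            friction_coefficient=m.get("mu", 0.1),
            foundation_thickness=m.get("h_mm", 2.0),
        )
        return cls(
            upper,
            lower,
            ToothLabelMap(
                np.round(upper.face_fields.pop("tooth")).astype(np.int64)
            ),
            ToothLabelMap(
                np.round(lower.face_fields.pop("tooth")).astype(np.int64)
            ),
            material,
            info.get("meta", {}) or {},
        )


# ---------------------------------------------------------------------
# tooth labelling from an arch specification


@dataclass
class ArchSpec:
    """Arch curve plus mesial-distal tooth intervals for labelling.

    ``curve`` is a dense polyline of the mid-arch curve for the right
    half (arc parameter s >= 0, mirrored for the left side).
    ``intervals`` maps position index (1..8) to its (s_mesial, s_distal)
    arc-length span; ``quadrants`` gives the (right, left) FDI quadrant
    digits of the arch.
    """

    curve: np.ndarray  # (k, 3), s >= 0 half
    arc: np.ndarray  # (k,) cumulative arc length of `curve`
    intervals: dict  # position -> (s_mesial, s_distal)
    quadrants: tuple  # e.g. (4, 3) for the mandible

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1 - 1e-12:
                raise LabelError(
                    f"overlapping tooth intervals ({a0:.3f},{a1:.3f}) and "
                    f"({b0:.3f},{b1:.3f})"
                )

    def arc_parameter(self, points: np.ndarray) -> np.ndarray:
        """Unsigned arc parameter |s| of the nearest curve point."""
        p = np.asarray(points, dtype=np.float64).copy()
        p[:, 0] = np.abs(p[:, 0])  # fold onto the right half
        p[:, 1] = 0.0
        flat = self.curve.copy()
        flat[:, 1] = 0.0
        d = np.linalg.norm(p[:, None, :] - flat[None, :, :], axis=2)
        return self.arc[np.argmin(d, axis=1)]


def assign_tooth_labels(mesh: SurfaceMesh, arch_spec: ArchSpec) -> ToothLabelMap:
    """Label every face by the tooth interval containing its centroid.

    A centroid exactly on a mesial-distal boundary goes to the mesial
    (closer-to-midline) tooth. Faces outside every interval get 0.
    """
    if mesh.n_faces == 0:
        return ToothLabelMap(np.empty(0, dtype=np.int64))
    centroids = mesh.face_centroids()
    s = arch_spec.arc_parameter(centroids)
    side_right = centroids[:, 0] >= 0.0
    labels = np.zeros(mesh.n_faces, dtype=np.int64)
    positions = sorted(arch_spec.intervals)
    bounds = np.array([arch_spec.intervals[p][1] for p in positions])
    starts = np.array([arch_spec.intervals[p][0] for p in positions])
    idx = np.searchsorted(bounds, s, side="left")
    ok = (idx < len(positions)) & (s >= starts[np.minimum(idx, len(positions) - 1)])
    qr, ql = arch_spec.quadrants
    for i in np.nonzero(ok)[0]:
        pos = positions[idx[i]]
        labels[i] = 10 * (qr if side_right[i] else ql) + pos
    return ToothLabelMap(labels)


# ---------------------------------------------------------------------
# virtual occlusal carving


def carve_region(
    mesh: SurfaceMesh, labels: ToothLabelMap, spec: ModificationSpec
) -> SurfaceMesh:
    """Virtually remove occlusal material on one tooth.

    Only vertices that (a) lie inside the spherical region and (b)
    belong to at least one face carrying ``spec.target_label`` are
    displaced, along ``-removal_direction``, by
    ``removal_depth * 0.5 * (1 + cos(pi * d / radius))`` where ``d`` is
    the distance to the region centre. Connectivity is unchanged; all
    other vertices are untouched exactly.
    """
    if len(labels) != mesh.n_faces:
        raise LabelError("label count != face count")
    out = mesh.copy()
    if spec.removal_depth == 0.0:
        return out

    target_faces = labels.faces_of(spec.target_label)
    on_target = np.zeros(mesh.n_vertices, dtype=bool)
    for row in mesh.faces[target_faces]:
        for v in row:
            if v >= 0:
                on_target[v] = True

    d = np.linalg.norm(mesh.vertices - spec.center[None, :], axis=1)
    inside = d < spec.radius
    sel = inside & on_target
    if not np.any(sel):
        warnings.warn(
            f"carve region intersects no face labelled {spec.target_label}; "
            "mesh returned unchanged",
            stacklevel=2,
        )
        return out
    taper = spec.removal_depth * 0.5 * (1.0 + np.cos(np.pi * d[sel] / spec.radius))
    out.vertices[sel] -= taper[:, None] * spec.removal_direction[None, :]
    out.bump_version()
    return out
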