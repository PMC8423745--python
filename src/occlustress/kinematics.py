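"""Jaw-motion recording types and rigid-trajectory construction.

Two recording modalities are fused: a high-rate (nominally 1000 Hz)
3-D displacement trace of the incisal magnet point, and low-rate
(video frame rate) per-plane rotation angles obtained from fixed/
movable landmark marker pairs. Both streams start at the centric
(intercuspal) reference pose; the common task interval is split into
equal time bins and the interpolated bin-end displacement plus the
three bin-end plane angles form one absolute rigid transform per
segment, all expressed in the centric reference frame.

Rotation composition (fixed and documented):
``R = R_hor(theta_hor) @ R_fro(theta_fro) @ R_sag(theta_sag)`` with
sagittal = rotation about +x (viewed from the subject's right),
frontal = rotation about +z (viewed from anterior) and horizontal =
rotation about +y (viewed from above); counter-clockwise positive in
each stated view. Angles are radians throughout (``angle_unit`` flags
on the loaders accept degrees).

Point action of a transform: ``p -> R @ (p - c) + c + t`` with rotation
centre ``c`` (default: the incisal reference point, i.e. the origin).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateVectorError,
    ParameterError,
    ResolutionError,
    SamplingError,
    SchemaError,
)

__all__ = [
    "TASKS",
    "TASK_SEGMENTS",
    "TASK_PRESETS",
    "DisplacementTrace",
    "MarkerTrack",
    "RotationTrace",
    "RigidTransform",
    "TrajectorySegment",
    "MergedTrajectory",
    "compose_transform",
    "rotation_matrix",
    "load_displacement_trace",
    "save_displacement_trace",
    "load_marker_tracks",
    "save_marker_tracks",
    "extract_plane_angle",
    "combine_rotation_traces",
    "segment_and_merge",
    "mirror_trace",
    "generate_synthetic_recording",
]

log = logging.getLogger(__name__)

TASKS = ("centric_closing", "protrusion", "right_excursion", "left_excursion")

# merged-segment counts per task (recording-protocol defaults)
TASK_SEGMENTS = {
    "centric_closing": 18,
    "protrusion": 61,
    "left_excursion": 29,
    "right_excursion": 35,
}

# endpoint displacement (mm) and (sagittal, frontal, horizontal) angles
# (rad) of the built-in synthetic task presets; amplitudes follow the
# recorded envelope of the study subject. Signs encode her movement
# strategy: the right excursion keeps the posterior teeth gliding
# (sagittal lift), the shorter left excursion drops them slightly.
TASK_PRESETS = {
    "centric_closing": ((0.0, -0.8, 0.3), (0.104, 0.001, 0.003)),
    "protrusion": ((0.0, -1.0, 8.0), (-0.111, 0.002, 0.001)),
    "right_excursion": ((6.9, -6.6, -0.3), (0.084, 0.001, -0.471)),
    "left_excursion": ((-4.1, -1.9, -0.3), (-0.052, -0.002, 0.179)),
}

_PLANES = ("sagittal", "frontal", "horizontal")
_MARKER_PAIRS = {
    "sagittal": ("RZP", "gonion"),
    "frontal": ("nasion", "pogonion"),
    "horizontal": ("hyoid", "pogonion"),
}


# ---------------------------------------------------------------------
# trace types


@dataclass
class DisplacementTrace:
    """Uniform 3-D incisal displacement trace relative to centric."""

    times: np.ndarray  # (n,) s
    displacements: np.ndarray  # (n, 3) mm
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise SamplingError("sampling_rate must be > 0")
        if len(self.times) < 2:
            raise SamplingError("need at least 2 samples")
        dt = np.diff(self.times)
        if dt.min() <= 0:
            raise SamplingError("times must be strictly increasing")
        if np.abs(dt - 1.0 / self.sampling_rate).max() > 1e-6:
            raise SamplingError(
                "non-uniform sampling: max timestamp jitter "
                f"{np.abs(dt - dt.mean()).max():.3e} s exceeds 1e-6 s"
            )
        if np.abs(self.displacements[0]).max() > 1e-12:
            raise SamplingError(
                "first displacement sample must be (0, 0, 0); re-base the "
                "trace (load_displacement_trace does this automatically)"
            )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the displacement at time(s) t."""
        t = np.atleast_1d(t)
        return np.column_stack(
            [
                np.interp(t, self.times, self.displacements[:, i])
                for i in range(3)
            ]
        )


@dataclass
class MarkerTrack:
    """Per-frame 2-D image positions of one fixed/movable landmark pair."""

    plane: str
    fixed_name: str
    movable_name: str
    times: np.ndarray  # (n,) s
    fixed_xy: np.ndarray  # (n, 2) px
    movable_xy: np.ndarray  # (n, 2) px
    frame_rate: float

    def __post_init__(self) -> None:
        if self.plane not in _PLANES:
            raise SchemaError(f"unknown plane {self.plane!r}")
        expect = _MARKER_PAIRS[self.plane]
        if (self.fixed_name, self.movable_name) != expect:
            raise SchemaError(
                f"{self.plane} plane uses fixed={expect[0]!r} "
                f"movable={expect[1]!r}, got ({self.fixed_name!r}, "
                f"{self.movable_name!r})"
            )
        self.times = np.asarray(self.times, dtype=np.float64)
        self.fixed_xy = np.asarray(self.fixed_xy, dtype=np.float64)
        self.movable_xy = np.asarray(self.movable_xy, dtype=np.float64)
        if len(self.times) < 2:
            raise SamplingError("marker track needs >= 2 frames")


@dataclass
class RotationTrace:
    """Aligned per-plane angle series (radians, 0 at centric)."""

    times: np.ndarray  # (n,) s
    angles: np.ndarray  # (n, 3): sagittal, frontal, horizontal
    frame_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if np.abs(self.angles[0]).max() > 1e-12:
            raise SamplingError("angles must be 0 at the first frame")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t) -> np.ndarray:
        t = np.atleast_1d(t)
        return np.column_stack(
            [np.interp(t, self.times, self.angles[:, i]) for i in range(3)]
        )


# ---------------------------------------------------------------------
# rigid transforms


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(theta_sag: float, theta_fro: float, theta_hor: float):
    """Composed rotation ``R_hor @ R_fro @ R_sag`` (fixed order)."""
    return _ry(theta_hor) @ _rz(theta_fro) @ _rx(theta_sag)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a centre followed by a translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rotation_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = self.rotation_center
        return (p - c) @ self.rotation.T + c + self.translation

    @property
    def orthonormality_error(self) -> float:
        r = self.rotation
        return float(np.abs(r.T @ r - np.eye(3)).max())


def compose_transform(
    theta_sag: float,
    theta_fro: float,
    theta_hor: float,
    translation,
    rotation_center=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """Build the rigid transform for one merged segment."""
    return RigidTransform(
        rotation_matrix(theta_sag, theta_fro, theta_hor),
        np.asarray(translation, dtype=np.float64),
        np.asarray(rotation_center, dtype=np.float64),
    )


@dataclass
class TrajectorySegment:
    """One merged time bin: absolute pose at the bin end."""

    t_start: float
    t_end: float
    translation: np.ndarray  # (3,) mm
    angles: np.ndarray  # (3,) rad: sagittal, frontal, horizontal

    def transform(self, rotation_center=(0.0, 0.0, 0.0)) -> RigidTransform:
        return compose_transform(
            self.angles[0],
            self.angles[1],
            self.angles[2],
            self.translation,
            rotation_center,
        )


@dataclass
class MergedTrajectory:
    """Ordered contiguous segments of absolute lower-arch poses."""

    segments: list
    task: str | None = None
    rotation_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ParameterError("trajectory needs >= 1 segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.t_end, b.t_start, atol=1e-9):
                raise ParameterError("segments must be contiguous")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def transforms(self) -> list:
        return [s.transform(self.rotation_center) for s in self.segments]

    # -- CSV export: segment,t_start,t_end,tx,ty,tz,theta_* ------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.segments, 1):
            rows.append(
                {
                    "segment": i,
                    "t_start": s.t_start,
                    "t_end": s.t_end,
                    "tx": s.translation[0],
                    "ty": s.translation[1],
                    "tz": s.translation[2],
                    "theta_sag": s.angles[0],
                    "theta_fro": s.angles[1],
                    "theta_hor": s.angles[2],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, task=None) -> "MergedTrajectory":
        df = pd.read_csv(path)
        need = {"segment", "t_start", "t_end", "tx", "ty", "tz",
                "theta_sag", "theta_fro", "theta_hor"}
        if not need.issubset(df.columns):
            raise SchemaError(
                f"trajectory CSV missing columns {sorted(need - set(df.columns))}"
            )
        segs = [
            TrajectorySegment(
                float(r.t_start),
                float(r.t_end),
                np.array([r.tx, r.ty, r.tz]),
                np.array([r.theta_sag, r.theta_fro, r.theta_hor]),
            )
            for r in df.sort_values("segment").itertuples()
        ]
        return cls(segs, task=task)


# ---------------------------------------------------------------------
# loading and saving trace CSVs


def load_displacement_trace(path, angle_unit: str = "rad") -> DisplacementTrace:
    """Read a ``t,dx,dy,dz`` CSV (s, mm); re-bases a non-zero first sample."""
    df = pd.read_csv(path)
    need = ["t", "dx", "dy", "dz"]
    if list(df.columns[:4]) != need:
        raise SchemaError(
            f"{path}: displacement CSV must have columns {need}, "
            f"got {list(df.columns)}"
        )
    t = df["t"].to_numpy(dtype=np.float64)
    d = df[["dx", "dy", "dz"]].to_numpy(dtype=np.float64)
    if np.abs(d[0]).max() > 0:
        log.info(
            "re-based displacement trace %s by offset %s mm", path, d[0]
        )
        d = d - d[0]
    if len(t) < 2:
        raise SamplingError(f"{path}: need at least 2 samples")
    rate = 1.0 / np.median(np.diff(t))
    return DisplacementTrace(t - t[0], d, float(rate))


def save_displacement_trace(trace: DisplacementTrace, path) -> None:
    pd.DataFrame(
        {
            "t": trace.times,
            "dx": trace.displacements[:, 0],
            "dy": trace.displacements[:, 1],
            "dz": trace.displacements[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def load_rotation_trace(path, angle_unit: str = "rad") -> RotationTrace:
    """Read a ``t,theta_sag,theta_fro,theta_hor`` CSV (s, radians)."""
    df = pd.read_csv(path)
    need = ["t", "theta_sag", "theta_fro", "theta_hor"]
    if list(df.columns[:4]) != need:
        raise SchemaError(
            f"{path}: rotation CSV must have columns {need}, "
            f"got {list(df.columns)}"
        )
    t = df["t"].to_numpy(dtype=np.float64)
    a = df[need[1:]].to_numpy(dtype=np.float64)
    if angle_unit == "deg":
        a = np.deg2rad(a)
    elif angle_unit != "rad":
        raise SchemaError("angle_unit must be 'rad' or 'deg'")
    if len(t) < 2:
        raise SamplingError(f"{path}: need at least 2 frames")
    a = a - a[0]
    return RotationTrace(t - t[0], a, float(1.0 / np.median(np.diff(t))))


def save_rotation_trace(rot: RotationTrace, path) -> None:
    pd.DataFrame(
        {
            "t": rot.times,
            "theta_sag": rot.angles[:, 0],
            "theta_fro": rot.angles[:, 1],
            "theta_hor": rot.angles[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def load_marker_tracks(path, frame_rate: float | None = None) -> dict:
    """Read a ``t,plane,fixed_u,fixed_v,mov_u,mov_v`` CSV into tracks."""
    df = pd.read_csv(path)
    need = {"t", "plane", "fixed_u", "fixed_v", "mov_u", "mov_v"}
    if not need.issubset(df.columns):
        raise SchemaError(
            f"{path}: marker CSV missing columns {sorted(need - set(df.columns))}"
        )
    out = {}
    for plane, sub in df.groupby("plane"):
        sub = sub.sort_values("t")
        t = sub["t"].to_numpy(dtype=np.float64)
        rate = frame_rate or 1.0 / np.median(np.diff(t))
        fixed, movable = _MARKER_PAIRS[str(plane)]
        out[str(plane)] = MarkerTrack(
            str(plane),
            fixed,
            movable,
            t - t[0],
            sub[["fixed_u", "fixed_v"]].to_numpy(dtype=np.float64),
            sub[["mov_u", "mov_v"]].to_numpy(dtype=np.float64),
            float(rate),
        )
    return out


def save_marker_tracks(tracks: dict, path) -> None:
    frames = []
    for plane in _PLANES:
        if plane not in tracks:
            continue
        tr = tracks[plane]
        frames.append(
            pd.DataFrame(
                {
                    "t": tr.times,
                    "plane": plane,
                    "fixed_u": tr.fixed_xy[:, 0],
                    "fixed_v": tr.fixed_xy[:, 1],
                    "mov_u": tr.movable_xy[:, 0],
                    "mov_v": tr.movable_xy[:, 1],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------
# angle extraction and merging


def extract_plane_angle(track: MarkerTrack) -> np.ndarray:
    """Signed plane angle per frame of the movable-fixed vector.

    theta(t) is the angle from the frame-0 vector to the frame-t vector
    (counter-clockwise positive in image coordinates); theta(0) = 0.
    """
    v = track.movable_xy - track.fixed_xy
    norms = np.linalg.norm(v, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if len(bad):
        raise DegenerateVectorError(
            f"fixed and movable markers coincide at frame {int(bad[0])} "
            f"(t={track.times[int(bad[0])]:.4f} s) in {track.plane} plane"
        )
    v0 = v[0]
    cross = v0[0] * v[:, 1] - v0[1] * v[:, 0]
    dot = v @ v0
    theta = np.unwrap(np.arctan2(cross, dot))
    return theta - theta[0]


def combine_rotation_traces(tracks: dict) -> RotationTrace:
    """Extract all three plane angles onto the sagittal track's timebase."""
    missing = [p for p in _PLANES if p not in tracks]
    if missing:
        raise CoverageError(f"missing marker tracks for planes {missing}")
    ref = tracks["sagittal"]
    t = ref.times
    cols = []
    for plane in _PLANES:
        tr = tracks[plane]
        theta = extract_plane_angle(tr)
        if len(tr.times) != len(t) or np.abs(tr.times - t).max() > 0.5 / ref.frame_rate:
            theta = np.interp(t, tr.times, theta)
        cols.append(theta)
    return RotationTrace(t, np.column_stack(cols), ref.frame_rate)


def segment_and_merge(
    disp: DisplacementTrace,
    rot: RotationTrace,
    n_segments: int,
    rotation_center=(0.0, 0.0, 0.0),
    task: str | None = None,
) -> MergedTrajectory:
    """Fuse the two streams into an n-segment rigid trajectory.

    The common interval is split into equal time bins; each segment's
    pose is the linearly interpolated displacement and plane angles at
    its bin end, expressed in the centric reference frame (absolute,
    not incremental).
    """
    if n_segments < 1:
        raise ParameterError("n_segments must be >= 1")
    if n_segments > len(disp.times):
        raise ResolutionError(
            f"n_segments={n_segments} exceeds the {len(disp.times)} "
            "displacement samples"
        )
    frame_dt = 1.0 / rot.frame_rate
    if disp.duration - rot.duration > frame_dt + 1e-9:
        raise CoverageError(
            f"rotation trace ({rot.duration:.3f} s) is shorter than the "
            f"displacement trace ({disp.duration:.3f} s) by more than one "
            f"video frame ({frame_dt:.3f} s)"
        )
    t_end = min(disp.duration, rot.duration)
    edges = np.linspace(0.0, t_end, n_segments + 1)
    d = disp.at(edges[1:])
    a = rot.at(edges[1:])
    segments = [
        TrajectorySegment(edges[i], edges[i + 1], d[i], a[i])
        for i in range(n_segments)
    ]
    return MergedTrajectory(
        segments, task=task, rotation_center=np.asarray(rotation_center, float)
    )


_MIRROR_TASK = {
    "right_excursion": "left_excursion",
    "left_excursion": "right_excursion",
}


def mirror_trace(traj: MergedTrajectory) -> MergedTrajectory:
    """Reflect a trajectory about the mid-sagittal plane (x = 0).

    Per segment: dx is negated, dy/dz kept; the frontal and horizontal
    angles are negated, the sagittal angle kept. Excursion task labels
    swap sides. An exact involution.
    """
    if traj.task is not None and traj.task not in _MIRROR_TASK:
        warnings.warn(
            f"mirroring a {traj.task} trajectory (mirror is defined but "
            "the task is not side-specific)",
            stacklevel=2,
        )
    segs = [
        TrajectorySegment(
            s.t_start,
            s.t_end,
            s.translation * np.array([-1.0, 1.0, 1.0]),
            s.angles * np.array([1.0, -1.0, -1.0]),
        )
        for s in traj.segments
    ]
    center = traj.rotation_center * np.array([-1.0, 1.0, 1.0])
    return MergedTrajectory(
        segs, task=_MIRROR_TASK.get(traj.task, traj.task), rotation_center=center
    )


# ---------------------------------------------------------------------
# synthetic recordings


def _min_jerk(u: np.ndarray) -> np.ndarray:
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def generate_synthetic_recording(
    task: str,
    displacement_end=None,
    angles_end=None,
    duration: float = 1.0,
    displacement_rate: float = 1000.0,
    video_rate: float = 30.0,
    marker_noise_px: float = 0.0,
    marker_baseline_px: float = 1000.0,
    profile: str = "minimum_jerk",
    seed: int = 0,
) -> tuple:
    """Render a synthetic (displacement trace, marker tracks) pair.

    The underlying trajectory ramps from the centric pose to the task
    endpoint with a minimum-jerk (default) or constant-rate (``linear``)
    profile. Marker tracks are rendered by rotating an idealised
    movable landmark about its fixed partner by the plane's rotation
    angle, with optional Gaussian pixel jitter on both landmarks.
    Deterministic per seed.

    Returns ``(DisplacementTrace, {plane: MarkerTrack})``.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if task not in TASK_PRESETS:
        raise ParameterError(f"unknown task {task!r}; choose from {TASKS}")
    if profile not in ("minimum_jerk", "linear"):
        raise ParameterError("profile must be 'minimum_jerk' or 'linear'")
    d_end = np.asarray(
        TASK_PRESETS[task][0] if displacement_end is None else displacement_end,
        dtype=np.float64,
    )
    a_end = np.asarray(
        TASK_PRESETS[task][1] if angles_end is None else angles_end,
        dtype=np.float64,
    )
    rng = np.random.default_rng(seed)

    n_d = int(round(duration * displacement_rate)) + 1
    t_d = np.arange(n_d) / displacement_rate
    u = t_d / duration
    sig = u if profile == "linear" else _min_jerk(u)
    disp = DisplacementTrace(t_d, sig[:, None] * d_end[None, :], displacement_rate)

    n_v = int(round(duration * video_rate)) + 1
    t_v = np.arange(n_v) / video_rate
    uv = t_v / duration
    sig_v = uv if profile == "linear" else _min_jerk(uv)

    tracks = {}
    for j, plane in enumerate(_PLANES):
        fixed0 = np.array([200.0, 300.0])
        base = np.array([marker_baseline_px, 0.0])
        theta = sig_v * a_end[j]
        c, s = np.cos(theta), np.sin(theta)
        mov = fixed0[None, :] + np.column_stack(
            [c * base[0] - s * base[1], s * base[0] + c * base[1]]
        )
        fixed = np.broadcast_to(fixed0, (n_v, 2)).copy()
        if marker_noise_px > 0:
            fixed = fixed + rng.normal(0, marker_noise_px, (n_v, 2))
            mov = mov + rng.normal(0, marker_noise_px, (n_v, 2))
        fname, mname = _MARKER_PAIRS[plane]
        tracks[plane] = MarkerTrack(
            plane, fname, mname, t_v, fixed, mov, video_rate
        )
    return disp, tracks
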