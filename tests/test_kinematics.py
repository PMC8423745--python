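"""Recording ingestion, angle extraction, merging and mirroring."""

import numpy as np
import pytest

from occlustress.errors import (
    CoverageError,
    DegenerateVectorError,
    ParameterError,
    ResolutionError,
    SchemaError,
)
from occlustress.kinematics import (
    TASK_PRESETS,
    DisplacementTrace,
    MarkerTrack,
    MergedTrajectory,
    RotationTrace,
    TrajectorySegment,
    combine_rotation_traces,
    compose_transform,
    extract_plane_angle,
    generate_synthetic_recording,
    load_displacement_trace,
    load_rotation_trace,
    mirror_trace,
    rotation_matrix,
    save_rotation_trace,
    segment_and_merge,
)


class TestDisplacementTrace:
    def test_csv_parse(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("t,dx,dy,dz\n0,0,0,0\n0.001,0.1,0,0\n0.002,0.2,0,0\n")
        tr = load_displacement_trace(path)
        assert tr.sampling_rate == pytest.approx(1000.0)
        assert tr.displacements[-1, 0] == pytest.approx(0.2)

    def test_rebase_nonzero_first_sample(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("t,dx,dy,dz\n0,1,1,1\n0.001,1.1,1,1\n")
        tr = load_displacement_trace(path)
        assert np.array_equal(tr.displacements[0], np.zeros(3))
        assert tr.displacements[1, 0] == pytest.approx(0.1)

    def test_schema_error(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("time,x\n0,0\n1,1\n")
        with pytest.raises(SchemaError):
            load_displacement_trace(path)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(Exception):
            DisplacementTrace(
                np.array([0.0, 0.001, 0.005]), np.zeros((3, 3)), 1000.0
            )


class TestPlaneAngle:
    def make_track(self, mov):
        n = len(mov)
        return MarkerTrack(
            "sagittal",
            "RZP",
            "gonion",
            np.arange(n) / 30.0,
            np.zeros((n, 2)),
            np.asarray(mov, dtype=float),
            30.0,
        )

    def test_angle_definition(self):
        track = self.make_track([[10, 0], [10, 1]])
        theta = extract_plane_angle(track)
        assert theta[0] == 0.0
        assert theta[1] == pytest.approx(np.arctan2(1, 10))

    def test_stationary_marker_zero(self):
        track = self.make_track([[10, 0]] * 5)
        assert np.array_equal(extract_plane_angle(track), np.zeros(5))

    def test_coincident_markers_named_frame(self):
        track = self.make_track([[10, 0], [0, 0], [10, 1]])
        with pytest.raises(DegenerateVectorError, match="frame 1"):
            extract_plane_angle(track)

    def test_programmed_horizontal_angle_recovered(self):
        """The recorded 0.471 rad excursion rotation is recovered."""
        _, tracks = generate_synthetic_recording("right_excursion", seed=0)
        theta = extract_plane_angle(tracks["horizontal"])
        assert abs(abs(theta[-1]) - 0.471) < 1e-3

    def test_noiseless_render_recovers_all_angles_exactly(self):
        _, tracks = generate_synthetic_recording("left_excursion", seed=0)
        a_end = np.array(TASK_PRESETS["left_excursion"][1])
        for i, plane in enumerate(("sagittal", "frontal", "horizontal")):
            theta = extract_plane_angle(tracks[plane])
            assert abs(theta[-1] - a_end[i]) < 1e-9


class TestSegmentAndMerge:
    def test_zero_motion_identity(self):
        disp = DisplacementTrace(
            np.arange(101) / 100.0, np.zeros((101, 3)), 100.0
        )
        rot = RotationTrace(np.arange(31) / 30.0, np.zeros((31, 3)), 30.0)
        traj = segment_and_merge(disp, rot, 7)
        for T in traj.transforms():
            assert np.allclose(T.rotation, np.eye(3), atol=1e-15)
            assert np.allclose(T.translation, 0.0)

    def test_linear_translation_chaining(self):
        """6.9 mm linear x-ramp over 29 segments splits as 6.9*k/29."""
        n = 1001
        t = np.arange(n) / 1000.0
        disp = DisplacementTrace(
            t, np.outer(t, [6.9, 0, 0]), 1000.0
        )
        rot = RotationTrace(np.arange(31) / 30.0, np.zeros((31, 3)), 30.0)
        traj = segment_and_merge(disp, rot, 29)
        for k, seg in enumerate(traj.segments, 1):
            assert abs(seg.translation[0] - 6.9 * k / 29) < 1e-9
            assert np.abs(seg.translation[1:]).max() < 1e-12

    def test_recovery_from_smooth_recording(self):
        """Forward-render (minimum jerk) then recover within tolerance."""
        disp, tracks = generate_synthetic_recording("right_excursion", seed=2)
        rot = combine_rotation_traces(tracks)
        traj = segment_and_merge(disp, rot, 35)
        d_end = np.array(TASK_PRESETS["right_excursion"][0])
        a_end = np.array(TASK_PRESETS["right_excursion"][1])
        sig = lambda u: u**3 * (10 - 15 * u + 6 * u**2)
        for seg in traj.segments:
            f = sig(seg.t_end)
            assert np.abs(seg.translation - f * d_end).max() < 0.01
            assert np.abs(seg.angles - f * a_end).max() < 1e-3

    def test_coverage_error(self):
        disp = DisplacementTrace(
            np.arange(1001) / 1000.0, np.zeros((1001, 3)), 1000.0
        )
        rot = RotationTrace(np.arange(16) / 30.0, np.zeros((16, 3)), 30.0)
        with pytest.raises(CoverageError):
            segment_and_merge(disp, rot, 10)

    def test_resolution_error(self):
        disp = DisplacementTrace(np.arange(5) / 4.0, np.zeros((5, 3)), 4.0)
        rot = RotationTrace(np.arange(5) / 4.0, np.zeros((5, 3)), 4.0)
        with pytest.raises(ResolutionError):
            segment_and_merge(disp, rot, 50)


class TestComposeTransform:
    def test_identity(self):
        T = compose_transform(0, 0, 0, (0, 0, 0))
        assert np.array_equal(T.rotation, np.eye(3))
        assert T.apply([[1.0, 2.0, 3.0]])[0] == pytest.approx([1, 2, 3])

    def test_orthonormal_at_recorded_magnitudes(self):
        T = compose_transform(0.104, 0.001, 0.003, (0, -0.8, 0.3))
        assert T.orthonormality_error < 1e-12

    def test_distance_preservation(self):
        T = compose_transform(0.104, 0.001, 0.003, (1.0, -2.0, 0.5))
        tet = np.array(
            [[0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]]
        )
        out = T.apply(tet)
        for i in range(4):
            for j in range(i + 1, 4):
                d0 = np.linalg.norm(tet[i] - tet[j])
                d1 = np.linalg.norm(out[i] - out[j])
                assert abs(d0 - d1) < 1e-9

    def test_composition_order_sensitivity_bounded(self):
        """All 6 rotation orders agree within 0.05 mm at recorded angles."""
        import itertools

        from occlustress.kinematics import _rx, _ry, _rz

        mats = {
            "s": _rx(0.104),
            "f": _rz(0.001),
            "h": _ry(0.003),
        }
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        pts = 50.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        images = []
        for order in itertools.permutations("sfh"):
            R = mats[order[0]] @ mats[order[1]] @ mats[order[2]]
            images.append(pts @ R.T)
        worst = 0.0
        for i in range(len(images)):
            for j in range(i + 1, len(images)):
                worst = max(
                    worst,
                    np.linalg.norm(images[i] - images[j], axis=1).max(),
                )
        assert worst <= 0.05

    def test_rotation_center_shifts_action(self):
        c = np.array([0.0, 40.0, -100.0])
        T = compose_transform(0.1, 0, 0, (0, 0, 0), rotation_center=c)
        assert np.allclose(T.apply(c[None, :])[0], c)


class TestMirrorTrace:
    def make_traj(self, task="right_excursion"):
        segs = [
            TrajectorySegment(
                0.0, 0.5, np.array([6.9, -6.6, 0.0]), np.array([0.084, 0.001, -0.471])
            ),
            TrajectorySegment(
                0.5, 1.0, np.array([3.0, -2.0, 0.1]), np.array([0.05, 0.0, -0.2])
            ),
        ]
        return MergedTrajectory(segs, task=task)

    def test_reflection_rule(self):
        m = mirror_trace(self.make_traj())
        assert np.array_equal(m.segments[0].translation, [-6.9, -6.6, 0.0])
        assert np.array_equal(m.segments[0].angles, [0.084, -0.001, 0.471])
        assert m.task == "left_excursion"

    def test_involution_exact(self):
        traj = self.make_traj()
        back = mirror_trace(mirror_trace(traj))
        for a, b in zip(traj.segments, back.segments):
            assert np.array_equal(a.translation, b.translation)
            assert np.array_equal(a.angles, b.angles)
        assert back.task == traj.task

    def test_commutes_with_time_reversal(self):
        traj = self.make_traj()

        def reverse(t):
            segs = [
                TrajectorySegment(s.t_start, s.t_end, u.translation, u.angles)
                for s, u in zip(t.segments, reversed(t.segments))
            ]
            return MergedTrajectory(segs, task=t.task)

        a = mirror_trace(reverse(traj))
        b = reverse(mirror_trace(traj))
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.translation, sb.translation)
            assert np.array_equal(sa.angles, sb.angles)

    def test_non_excursion_warns(self):
        with pytest.warns(UserWarning):
            mirror_trace(self.make_traj(task="centric_closing"))

    def test_csv_round_trip(self, tmp_path):
        traj = self.make_traj()
        traj.to_csv(tmp_path / "t.csv")
        back = MergedTrajectory.from_csv(tmp_path / "t.csv", task=traj.task)
        for a, b in zip(traj.segments, back.segments):
            assert np.allclose(a.translation, b.translation, atol=1e-12)
            assert np.allclose(a.angles, b.angles, atol=1e-12)


class TestRotationTraceCSV:
    def test_round_trip(self, tmp_path):
        rot = RotationTrace(
            np.arange(4) / 30.0,
            np.vstack([np.zeros(3), np.full((3, 3), 0.01) * [[1], [2], [3]]]),
            30.0,
        )
        save_rotation_trace(rot, tmp_path / "r.csv")
        back = load_rotation_trace(tmp_path / "r.csv")
        assert np.allclose(back.angles, rot.angles, atol=1e-12)

    def test_degrees_flag(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "t,theta_sag,theta_fro,theta_hor\n0,0,0,0\n0.1,90,0,0\n"
        )
        rot = load_rotation_trace(path, angle_unit="deg")
        assert rot.angles[1, 0] == pytest.approx(np.pi / 2)


class TestSyntheticRecording:
    def test_presets_match_recorded_envelope(self):
        disp, tracks = generate_synthetic_recording("right_excursion", seed=0)
        assert disp.displacements[-1, 0] == pytest.approx(6.9)
        assert disp.displacements[-1, 1] == pytest.approx(-6.6)
        theta_h = extract_plane_angle(tracks["horizontal"])
        assert abs(theta_h[-1]) == pytest.approx(0.471, abs=1e-9)

    def test_left_preset_amplitudes(self):
        disp, _ = generate_synthetic_recording("left_excursion", seed=0)
        assert disp.displacements[-1, 0] == pytest.approx(-4.1)
        assert disp.displacements[-1, 1] == pytest.approx(-1.9)

    def test_zero_duration_rejected(self):
        with pytest.raises(ParameterError):
            generate_synthetic_recording("protrusion", duration=0.0)

    def test_noise_is_seeded(self):
        _, a = generate_synthetic_recording(
            "protrusion", marker_noise_px=0.5, seed=4
        )
        _, b = generate_synthetic_recording(
            "protrusion", marker_noise_px=0.5, seed=4
        )
        assert np.array_equal(
            a["sagittal"].movable_xy, b["sagittal"].movable_xy
        )
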