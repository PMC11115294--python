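"""Feature extraction: filtering, segmentation, segment bases, angles."""

import numpy as np
import pytest

from occireach import kinematics, simulate
from occireach.errors import (
    DegenerateFrameError,
    InvalidArgumentError,
    MissingMarkerError,
    NoMotionDetectedError,
)
from occireach.kinematics import (
    ExtractionConfig,
    MotionBounds,
    angular_velocity,
    build_segment_bases,
    detect_motion_bounds,
    elbow_flexion,
    extract_features,
    joint_angles,
    lowpass_filter,
    marker_displacement,
    shoulder_angles,
)
from occireach.trial import TrialRecording

from conftest import make_noiseless_trial

FS = 100.0


def _sine(freq, n=1000, fs=FS):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)


class TestLowpassFilter:
    def test_dc_passthrough(self):
        x = np.full(500, 7.3)
        np.testing.assert_allclose(lowpass_filter(x, 6.0, FS), x, atol=1e-9)

    def test_passband_and_stopband_attenuation(self):
        passband = lowpass_filter(_sine(1.0), 6.0, FS)
        stopband = lowpass_filter(_sine(30.0), 6.0, FS)
        mid = slice(200, 800)  # avoid edge transients
        assert np.abs(passband[mid]).max() > 0.99
        assert np.abs(stopband[mid]).max() < 0.05

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lowpass_filter(np.zeros(100), 50.0, FS)

    def test_length_preserved(self):
        x = np.random.default_rng(0).normal(size=(345, 3))
        assert lowpass_filter(x, 6.0, FS).shape == (345, 3)


class TestDetectMotionBounds:
    def test_static_input_raises(self):
        xyz = np.tile([1.0, 2.0, 3.0], (500, 1))
        with pytest.raises(NoMotionDetectedError):
            detect_motion_bounds(xyz, FS, 5.0)

    def test_subthreshold_noise_raises(self, rng):
        # per-frame speeds stay below epsilon: never counts as movement
        xyz = rng.normal(scale=0.004, size=(500, 3))  # ~0.7 mm/s speeds
        with pytest.raises(NoMotionDetectedError):
            detect_motion_bounds(xyz, FS, 5.0)

    def test_noiseless_outward_duration_recovered(self, geometry):
        trial = make_noiseless_trial(geometry, outward=1.5, ret=1.5)
        out_b, ret_b = detect_motion_bounds(trial.marker("RFIN"), FS, 0.1)
        assert out_b.motor_time(FS) == pytest.approx(1.5, abs=0.02)
        assert ret_b.motor_time(FS) == pytest.approx(1.5, abs=0.02)
        # return phase starts after the hold at the occiput
        assert ret_b.onset_frame > out_b.end_frame

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MotionBounds(10, 10, "outward")


class TestSegmentBases:
    def test_zero_pose_arm_antiparallel_to_trunk_vertical(self, geometry):
        mk = simulate.forward_kinematics(geometry, 0, 0, 0)
        trial = TrialRecording("P", "paralyzed",
                               {k: v[None, :] for k, v in mk.items()})
        bases = build_segment_bases(trial)
        arm_long = -bases.upper_arm[0, :, 2]      # distal direction
        trunk_up = bases.trunk[0, :, 2]
        assert np.dot(arm_long, trunk_up) == pytest.approx(-1.0, abs=1e-12)

    def test_orthonormality_on_noisy_trial(self, small_cohort):
        bases = build_segment_bases(small_cohort[0])
        for b in (bases.trunk, bases.upper_arm, bases.forearm):
            gram = np.einsum("nij,nik->njk", b, b)
            assert np.abs(gram - np.eye(3)).max() < 1e-9

    def test_rigid_rotation_leaves_joint_angles_unchanged(self, geometry):
        trial = make_noiseless_trial(geometry, outward=1.0, ret=1.0)
        ref = joint_angles(trial)
        # arbitrary rigid rotation + translation of the whole lab frame
        rot = np.array([[0.36, 0.48, -0.8],
                        [-0.8, 0.6, 0.0],
                        [0.48, 0.64, 0.6]])
        shift = np.array([500.0, -200.0, 1000.0])
        moved = trial.map_markers(lambda xyz: xyz @ rot.T + shift)
        got = joint_angles(moved)
        np.testing.assert_allclose(got.shoulder_flex, ref.shoulder_flex, atol=1e-8)
        np.testing.assert_allclose(got.shoulder_abd, ref.shoulder_abd, atol=1e-8)
        np.testing.assert_allclose(got.elbow_flex, ref.elbow_flex, atol=1e-8)

    def test_missing_marker_named_in_error(self, geometry):
        mk = simulate.forward_kinematics(geometry, 0, 0, 0)
        mk.pop("RELB")
        trial = TrialRecording("P", "paralyzed",
                               {k: v[None, :] for k, v in mk.items()})
        with pytest.raises(MissingMarkerError, match="RELB"):
            build_segment_bases(trial)

    def test_collinear_markers_flag_frame(self, geometry):
        mk = {k: v[None, :] for k, v in
              simulate.forward_kinematics(geometry, 0, 0, 0).items()}
        mk["CLAV"] = mk["C7"].copy()  # anterior axis collapses
        trial = TrialRecording("P", "paralyzed", mk)
        with pytest.raises(DegenerateFrameError, match="frame 0"):
            build_segment_bases(trial)


class TestJointAngles:
    def test_zero_pose_all_zero(self, geometry):
        mk = simulate.forward_kinematics(geometry, 0, 0, 0)
        trial = TrialRecording("P", "paralyzed",
                               {k: v[None, :] for k, v in mk.items()})
        bases = build_segment_bases(trial)
        flex, abd = shoulder_angles(bases)
        assert flex[0] == pytest.approx(0.0, abs=1e-9)
        assert abd[0] == pytest.approx(0.0, abs=1e-9)
        assert elbow_flexion(bases)[0] == pytest.approx(0.0, abs=1e-6)

    def test_axis_isolation_pure_abduction(self, geometry):
        mk = simulate.forward_kinematics(geometry, 0, 90, 0)
        trial = TrialRecording("P", "paralyzed",
                               {k: v[None, :] for k, v in mk.items()})
        bases = build_segment_bases(trial)
        flex, abd = shoulder_angles(bases)
        assert flex[0] == pytest.approx(0.0, abs=1e-9)
        assert abd[0] == pytest.approx(90.0, abs=1e-9)
        assert elbow_flexion(bases)[0] == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_specific_triple(self, geometry):
        mk = simulate.forward_kinematics(geometry, 45, 20, 110)
        trial = TrialRecording("P", "paralyzed",
                               {k: v[None, :] for k, v in mk.items()})
        ang = joint_angles(trial)
        assert ang.shoulder_flex[0] == pytest.approx(45, abs=1e-6)
        assert ang.shoulder_abd[0] == pytest.approx(20, abs=1e-6)
        assert ang.elbow_flex[0] == pytest.approx(110, abs=1e-6)


class TestAngularVelocity:
    def test_constant_series_zero(self):
        np.testing.assert_array_equal(angular_velocity(np.full(10, 3.0), FS),
                                      np.zeros(10))

    def test_linear_ramp(self):
        ramp = np.linspace(0, 90, 101)
        vel = angular_velocity(ramp, FS)
        np.testing.assert_allclose(vel[1:-1], 90.0, atol=1e-9)

    def test_min_jerk_peak_closed_form(self):
        series = simulate.minimum_jerk_profile(0, 90, 1.0, FS)
        assert angular_velocity(series, FS).max() == pytest.approx(168.75, abs=0.5)

    def test_sign_preserved_on_descent(self):
        series = simulate.minimum_jerk_profile(90, 0, 1.0, FS)
        assert angular_velocity(series, FS).min() == pytest.approx(-168.75, abs=0.5)

    def test_too_short_series(self):
        with pytest.raises(InvalidArgumentError):
            angular_velocity(np.array([1.0, 2.0]), FS)


class TestMarkerDisplacement:
    def test_static_marker_zero(self):
        xyz = np.tile([5.0, 5.0, 5.0], (100, 1))
        assert marker_displacement(xyz, MotionBounds(0, 99, "outward")) == 0.0

    def test_pure_translation(self):
        xyz = np.zeros((100, 3))
        xyz[50:] = [10.0, 0.0, 0.0]
        assert marker_displacement(xyz, MotionBounds(0, 99, "outward")) == 10.0

    def test_random_walk_matches_exhaustive_scan(self, rng):
        xyz = np.cumsum(rng.normal(size=(200, 3)), axis=0)
        b = MotionBounds(20, 150, "outward")
        brute = max(float(np.linalg.norm(xyz[i] - xyz[20]))
                    for i in range(20, 151))
        assert marker_displacement(xyz, b) == pytest.approx(brute)


class TestExtractFeatures:
    def test_noiseless_peaks_recovered(self, geometry, noiseless_config):
        trial = make_noiseless_trial(geometry, flex=48.9, abd=117.5, elbow=134.2)
        out, ret = extract_features(trial, noiseless_config)
        for row in (out, ret):
            assert row.peak_shoulder_flex == pytest.approx(48.9, abs=0.5)
            assert row.peak_shoulder_abd == pytest.approx(117.5, abs=0.5)
            assert row.peak_elbow_flex == pytest.approx(134.2, abs=0.5)

    def test_zero_motion_trial_errors(self, geometry):
        mk = simulate.forward_kinematics(geometry, 0, 0, 0)
        trial = TrialRecording("P", "paralyzed",
                               {k: np.tile(v, (300, 1)) for k, v in mk.items()})
        with pytest.raises(NoMotionDetectedError):
            extract_features(trial, ExtractionConfig())

    def test_cohort_row_count(self, small_cohort):
        feats = kinematics.extract_cohort_features(small_cohort)
        # one outward + one return row per trial
        assert len(feats) == 2 * len(small_cohort)
        assert set(feats["phase"]) == {"outward", "return"}

    def test_peak_velocity_bounds_mean_speed(self, small_cohort):
        """Peak angular velocity can never undercut the phase-mean quotient."""
        trial = small_cohort[0]
        config = ExtractionConfig()
        filt = config.filtered(trial)
        out_b, _ = detect_motion_bounds(filt.marker(f"{trial.limb}FIN"),
                                        trial.sampling_rate,
                                        config.speed_eps_mm_s)
        ang = joint_angles(filt)
        out, _ = extract_features(trial, config)
        for series, peak in ((ang.shoulder_flex, out.peak_vel_shoulder_flex),
                             (ang.shoulder_abd, out.peak_vel_shoulder_abd),
                             (ang.elbow_flex, out.peak_vel_elbow_flex)):
            seg = series[out_b.slice]
            mean_quotient = (seg[-1] - seg[0]) / out_b.motor_time(
                trial.sampling_rate)
            assert peak >= mean_quotient - 1e-9

    def test_reproducible_across_runs(self, geometry, noiseless_config):
        trial = make_noiseless_trial(geometry)
        a = extract_features(trial, noiseless_config)
        b = extract_features(trial, noiseless_config)
        assert a[0].to_dict() == b[0].to_dict()
        assert a[1].to_dict() == b[1].to_dict()
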